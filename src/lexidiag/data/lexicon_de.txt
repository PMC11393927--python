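aber
abend
alle
alt
amsel
anfang
arbeit
arm
auge
aus
auto
bald
ball
baum
bein
berg
bild
blume
boden
brief
bringen
brot
bruder
buch
bunt
dach
damals
dann
dein
denken
ding
donner
dorf
drei
eben
eimer
eine
ende
enge
erde
essen
fahren
fall
falten
feld
fenster
fest
finden
fisch
flasche
fragen
frau
froh
garten
geben
gehen
geld
gern
gras
gut
haben
hafen
halten
hand
haus
heben
heute
himmel
hinter
hoch
holen
hund
immer
insel
jagen
jahr
jung
kalt
kind
klein
kommen
kopf
korb
kurz
lachen
laden
land
lange
laufen
leben
lehrer
leise
lesen
licht
liegen
loben
machen
malen
mann
maus
meer
mein
mild
minute
mond
morgen
mutter
nach
nacht
name
nase
neben
nehmen
nest
neu
oben
ofen
ohr
onkel
ort
osten
rasen
raten
regen
reise
rennen
ring
rot
rufen
runde
sagen
salz
sand
schnee
schon
schule
sehen
sein
selten
singen
sitzen
sommer
sonne
spielen
stein
stunde
tag
tal
tante
tasche
tief
tisch
tragen
tune
turm
uhr
und
unten
vater
vogel
voll
wagen
wald
wand
warm
wasser
weg
wein
weit
welt
wind
winter
wohnen
wolke
wort
zahl
zeit
zug
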
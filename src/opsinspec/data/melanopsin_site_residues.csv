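species,site,residue,expected_shift
mouse,152,F,
mouse,155,T,
mouse,158,I,
mouse,197,A,
mouse,302,F,
mouse,310,S,
mouse,311,T,
mouse,329,S,
13-lined ground squirrel,152,F,
13-lined ground squirrel,155,S,none
13-lined ground squirrel,158,I,
13-lined ground squirrel,197,A,
13-lined ground squirrel,302,F,
13-lined ground squirrel,310,S,
13-lined ground squirrel,311,I,blue
13-lined ground squirrel,329,S,
striped mouse,152,F,
striped mouse,155,T,
striped mouse,158,I,
striped mouse,197,A,
striped mouse,302,F,
striped mouse,310,A,blue
striped mouse,311,T,
striped mouse,329,S,
reindeer,152,F,
reindeer,155,T,
reindeer,158,I,
reindeer,197,A,
reindeer,302,F,
reindeer,310,S,
reindeer,311,T,
reindeer,329,N,red
golden hamster,152,F,
golden hamster,155,T,
golden hamster,158,I,
golden hamster,197,A,
golden hamster,302,F,
golden hamster,310,S,
golden hamster,311,T,
golden hamster,329,S,
human,152,F,
human,155,S,none
human,158,I,
human,197,A,
human,302,F,
human,310,S,
human,311,A,blue
human,329,S,
mole rat,152,S,none
mole rat,155,T,
mole rat,158,T,red
mole rat,197,A,
mole rat,302,F,
mole rat,310,S,
mole rat,311,T,
mole rat,329,N,red
rat,152,F,
rat,155,V,blue
rat,158,I,
rat,197,A,
rat,302,F,
rat,310,S,
rat,311,T,
rat,329,S,
horse,152,F,
horse,155,T,
horse,158,I,
horse,197,A,
horse,302,F,
horse,310,S,
horse,311,V,blue
horse,329,N,red
degu,152,F,
degu,155,T,
degu,158,I,
degu,197,A,
degu,302,F,
degu,310,S,
degu,311,T,
degu,329,N,red
crab-eating macaque,152,F,
crab-eating macaque,155,S,none
crab-eating macaque,158,I,
crab-eating macaque,197,A,
crab-eating macaque,302,F,
crab-eating macaque,310,S,
crab-eating macaque,311,A,blue
crab-eating macaque,329,S,
cow,152,F,
cow,155,T,
cow,158,I,
cow,197,A,
cow,302,F,
cow,310,S,
cow,311,T,
cow,329,N,red
sheep,152,F,
sheep,155,T,
sheep,158,I,
sheep,197,A,
sheep,302,F,
sheep,310,S,
sheep,311,T,
sheep,329,N,red
manatee,152,F,
manatee,155,T,
manatee,158,I,
manatee,197,A,
manatee,302,F,
manatee,310,S,
manatee,311,T,
manatee,329,N,red
cat,152,F,
cat,155,T,
cat,158,I,
cat,197,A,
cat,302,F,
cat,310,S,
cat,311,I,blue
cat,329,N,red
dog,152,F,
dog,155,T,
dog,158,I,
dog,197,A,
dog,302,F,
dog,310,S,
dog,311,A,blue
dog,329,N,red
fat-tailed dunnart,152,F,
fat-tailed dunnart,155,T,
fat-tailed dunnart,158,I,
fat-tailed dunnart,197,S,red
fat-tailed dunnart,302,F,
fat-tailed dunnart,310,S,
fat-tailed dunnart,311,T,
fat-tailed dunnart,329,N,red
rabbit,152,F,
rabbit,155,S,none
rabbit,158,I,
rabbit,197,A,
rabbit,302,F,
rabbit,310,S,
rabbit,311,T,
rabbit,329,N,red
bowhead whale,152,F,
bowhead whale,155,T,
bowhead whale,158,I,
bowhead whale,197,A,
bowhead whale,302,F,
bowhead whale,310,S,
bowhead whale,311,T,
bowhead whale,329,N,red
gerbil,152,F,
gerbil,155,T,
gerbil,158,I,
gerbil,197,A,
gerbil,302,F,
gerbil,310,S,
gerbil,311,T,
gerbil,329,N,red
horseshoe bat,152,F,
horseshoe bat,155,T,
horseshoe bat,158,I,
horseshoe bat,197,A,
horseshoe bat,302,F,
horseshoe bat,310,S,
horseshoe bat,311,T,
horseshoe bat,329,N,red
platypus,152,F,
platypus,155,T,
platypus,158,I,
platypus,197,S,red
platypus,302,Y,red
platypus,310,S,
platypus,311,V,blue
platypus,329,N,red
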
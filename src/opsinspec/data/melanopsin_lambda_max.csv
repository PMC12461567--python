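species,binomial,lambda_max_nm,se_nm
13-lined ground squirrel,Ictidomys tridecemlineatus,474,1.2
striped mouse,Rhabdomys pumilio,476,0.9
reindeer,Rangifer tarandus,477,1.0
golden hamster,Mesocricetus auratus,479,0.7
mouse,Mus musculus,480,1.1
human,Homo sapiens,481,1.1
mole rat,Nannospalax ehrenbergi,481,1.2
rat,Rattus norvegicus,481,1.1
horse,Equus caballus,482,0.9
degu,Octodon degus,482,1.2
crab-eating macaque,Macaca fascicularis,483,1.2
cow,Bos taurus,484,1.1
sheep,Ovis aries,484,1.1
manatee,Trichechus manatus,487,1.0
cat,Felis catus,488,1.0
dog,Canis lupus familiaris,488,0.9
fat-tailed dunnart,Sminthopsis crassicaudata,488,1.1
rabbit,Oryctolagus cuniculus,488,0.7
bowhead whale,Balaena mysticetus,489,1.2
gerbil,Meriones unguiculatus,491,1.0
horseshoe bat,Rhinolophus ferrumequinum,496,1.4
platypus,Ornithorhynchus anatinus,497,1.7
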
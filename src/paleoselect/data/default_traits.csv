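clade,protein_group,o2_capacity,circulatory,mineralogy,motility,buffered
foraminifera,diffusion,0,none,carbonate,non_motile,unbuffered
radiolarian,diffusion,0,none,siliceous,non_motile,unbuffered
sponge,diffusion,0,none,siliceous,non_motile,unbuffered
coral,diffusion,0,none,carbonate,non_motile,unbuffered
brachiopod,hemerythrin,1,open,carbonate,non_motile,unbuffered
bryozoan,hemerythrin,1,open,carbonate,non_motile,unbuffered
ostracod,hemocyanin,2,open,carbonate,motile,buffered
gastropod,hemocyanin,2,open,carbonate,motile,buffered
cephalopod,hemocyanin,2,closed,carbonate,motile,buffered
bivalve_protobranch,hemocyanin,2,open,carbonate,motile,buffered
bivalve_non_protobranch,hemoglobin,3,open,carbonate,motile,buffered
echinoderm,hemoglobin,3,open,carbonate,motile,unbuffered
conodont,hemoglobin,3,closed,phosphatic,motile,buffered
fish,hemoglobin,3,closed,phosphatic,motile,buffered
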
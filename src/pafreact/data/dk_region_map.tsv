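micro_region	hemisphere	macro_region
superiorfrontal	left	frontal
rostralmiddlefrontal	left	frontal
caudalmiddlefrontal	left	frontal
parsopercularis	left	frontal
parstriangularis	left	frontal
parsorbitalis	left	frontal
lateralorbitofrontal	left	frontal
medialorbitofrontal	left	frontal
precentral	left	frontal
paracentral	left	frontal
frontalpole	left	frontal
superiorparietal	left	parietal
inferiorparietal	left	parietal
supramarginal	left	parietal
postcentral	left	parietal
precuneus	left	parietal
superiortemporal	left	temporal
middletemporal	left	temporal
inferiortemporal	left	temporal
bankssts	left	temporal
fusiform	left	temporal
transversetemporal	left	temporal
entorhinal	left	temporal
temporalpole	left	temporal
parahippocampal	left	temporal
insula	left	temporal
lateraloccipital	left	occipital
lingual	left	occipital
pericalcarine	left	occipital
cuneus	left	occipital
caudalanteriorcingulate	left	cingulate
rostralanteriorcingulate	left	cingulate
posteriorcingulate	left	cingulate
isthmuscingulate	left	cingulate
superiorfrontal	right	frontal
rostralmiddlefrontal	right	frontal
caudalmiddlefrontal	right	frontal
parsopercularis	right	frontal
parstriangularis	right	frontal
parsorbitalis	right	frontal
lateralorbitofrontal	right	frontal
medialorbitofrontal	right	frontal
precentral	right	frontal
paracentral	right	frontal
frontalpole	right	frontal
superiorparietal	right	parietal
inferiorparietal	right	parietal
supramarginal	right	parietal
postcentral	right	parietal
precuneus	right	parietal
superiortemporal	right	temporal
middletemporal	right	temporal
inferiortemporal	right	temporal
bankssts	right	temporal
fusiform	right	temporal
transversetemporal	right	temporal
entorhinal	right	temporal
temporalpole	right	temporal
parahippocampal	right	temporal
insula	right	temporal
lateraloccipital	right	occipital
lingual	right	occipital
pericalcarine	right	occipital
cuneus	right	occipital
caudalanteriorcingulate	right	cingulate
rostralanteriorcingulate	right	cingulate
posteriorcingulate	right	cingulate
isthmuscingulate	right	cingulate
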
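parcel_id	hemisphere	x	y	z
lh.caudalanteriorcingulate	left	-0.001601	-0.160051	-0.987107
lh.caudalmiddlefrontal	left	-0.337878	0.132280	-0.931848
lh.cuneus	left	-0.363288	-0.365551	-0.856968
lh.entorhinal	left	-0.298044	0.592600	-0.748328
lh.fusiform	left	-0.690013	-0.057073	-0.721544
lh.inferiorparietal	left	-0.199026	-0.742135	-0.640019
lh.inferiortemporal	left	-0.641899	0.471127	-0.604983
lh.isthmuscingulate	left	-0.715764	-0.474113	-0.512736
lh.lateraloccipital	left	-0.152674	0.860278	-0.486429
lh.lateralorbitofrontal	left	-0.895018	0.195153	-0.401072
lh.lingual	left	-0.509854	-0.814278	-0.277490
lh.medialorbitofrontal	left	-0.548077	0.791745	-0.269724
lh.middletemporal	left	-0.952471	-0.252007	-0.171149
lh.parahippocampal	left	-0.106493	-0.987054	-0.119931
lh.paracentral	left	-0.880615	0.468988	-0.067576
lh.parsopercularis	left	-0.757504	-0.652701	-0.013042
lh.parsorbitalis	left	-0.320075	0.943083	0.090254
lh.parstriangularis	left	-0.992085	0.004589	0.125485
lh.pericalcarine	left	-0.330254	-0.916904	0.224097
lh.postcentral	left	-0.699912	0.671373	0.243683
lh.posteriorcingulate	left	-0.851991	-0.411475	0.323727
lh.precentral	left	-0.061846	0.915989	0.396407
lh.precuneus	left	-0.838358	0.293946	0.459076
lh.rostralanteriorcingulate	left	-0.528929	-0.691887	0.491453
lh.rostralmiddlefrontal	left	-0.401947	0.718705	0.567364
lh.superiorfrontal	left	-0.760306	-0.103651	0.641242
lh.superiorparietal	left	-0.161366	-0.703037	0.692603
lh.superiortemporal	left	-0.505054	0.352683	0.787740
lh.supramarginal	left	-0.427529	-0.306464	0.850470
lh.transversetemporal	left	-0.127249	0.486997	0.864084
lh.insula	left	-0.359329	0.054177	0.931637
rh.caudalanteriorcingulate	right	0.004874	-0.180274	-0.983604
rh.caudalmiddlefrontal	right	0.406590	0.165941	-0.898414
rh.cuneus	right	0.333003	-0.347301	-0.876636
rh.entorhinal	right	0.305049	0.591620	-0.746278
rh.fusiform	right	0.715203	-0.052911	-0.696912
rh.inferiorparietal	right	0.204588	-0.730986	-0.651002
rh.inferiortemporal	right	0.647035	0.486737	-0.586884
rh.isthmuscingulate	right	0.739621	-0.439098	-0.510052
rh.lateraloccipital	right	0.139551	0.878469	-0.456966
rh.lateralorbitofrontal	right	0.901819	0.182646	-0.391615
rh.lingual	right	0.500483	-0.809038	-0.308179
rh.medialorbitofrontal	right	0.586272	0.771294	-0.247770
rh.middletemporal	right	0.954168	-0.227166	-0.194831
rh.parahippocampal	right	0.118765	-0.984277	-0.130742
rh.paracentral	right	0.879066	0.472743	-0.061298
rh.parsopercularis	right	0.779212	-0.626640	-0.012280
rh.parsorbitalis	right	0.357748	0.932111	0.056441
rh.parstriangularis	right	0.987597	0.071085	0.139997
rh.pericalcarine	right	0.430934	-0.881951	0.190939
rh.postcentral	right	0.681650	0.694398	0.230576
rh.posteriorcingulate	right	0.866754	-0.388260	0.313035
rh.precentral	right	0.073371	0.913473	0.400229
rh.precuneus	right	0.848054	0.284647	0.446967
rh.rostralanteriorcingulate	right	0.530229	-0.674929	0.513154
rh.rostralmiddlefrontal	right	0.403858	0.696188	0.593482
rh.superiorfrontal	right	0.722304	-0.116727	0.681653
rh.superiorparietal	right	0.158281	-0.700961	0.695414
rh.superiortemporal	right	0.489497	0.344295	0.801158
rh.supramarginal	right	0.471318	-0.339242	0.814109
rh.transversetemporal	right	0.109091	0.407367	0.906725
rh.insula	right	0.326993	0.035721	0.944351
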
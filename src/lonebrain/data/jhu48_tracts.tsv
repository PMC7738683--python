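tract
Middle cerebellar peduncle
Pontine crossing tract
Genu of corpus callosum
Body of corpus callosum
Splenium of corpus callosum
Fornix (column and body)
Corticospinal tract R
Corticospinal tract L
Medial lemniscus R
Medial lemniscus L
Inferior cerebellar peduncle R
Inferior cerebellar peduncle L
Superior cerebellar peduncle R
Superior cerebellar peduncle L
Cerebral peduncle R
Cerebral peduncle L
Anterior limb of internal capsule R
Anterior limb of internal capsule L
Posterior limb of internal capsule R
Posterior limb of internal capsule L
Retrolenticular part of internal capsule R
Retrolenticular part of internal capsule L
Anterior corona radiata R
Anterior corona radiata L
Superior corona radiata R
Superior corona radiata L
Posterior corona radiata R
Posterior corona radiata L
Posterior thalamic radiation R
Posterior thalamic radiation L
Sagittal stratum R
Sagittal stratum L
External capsule R
External capsule L
Cingulum (cingulate gyrus) R
Cingulum (cingulate gyrus) L
Cingulum (hippocampus) R
Cingulum (hippocampus) L
Fornix (cres) / Stria terminalis R
Fornix (cres) / Stria terminalis L
Superior longitudinal fasciculus R
Superior longitudinal fasciculus L
Superior fronto-occipital fasciculus R
Superior fronto-occipital fasciculus L
Uncinate fasciculus R
Uncinate fasciculus L
Tapetum R
Tapetum L
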
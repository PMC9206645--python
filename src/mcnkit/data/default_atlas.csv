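roi,hemisphere,network
amygdala_left,left,SN
amygdala_right,right,SN
anterior_cingulate_cortex_left,left,SN
anterior_cingulate_cortex_right,right,SN
insula_left,left,SN
insula_right,right,SN
thalamus_left,left,SN
thalamus_right,right,SN
subthalamic_nucleus_left,left,SN
subthalamic_nucleus_right,right,SN
lentiform_nucleus_left,left,SN
lentiform_nucleus_right,right,SN
frontal_lobe_left,left,ECN
frontal_lobe_right,right,ECN
parietal_lobe_left,left,ECN
parietal_lobe_right,right,ECN
cerebellum_left,left,ECN
cerebellum_right,right,ECN
caudate_nucleus_left,left,ECN
caudate_nucleus_right,right,ECN
posterior_cingulate_gyrus_left,left,DMN
posterior_cingulate_gyrus_right,right,DMN
hippocampus_left,left,DMN
hippocampus_right,right,DMN
anterior_parahippocampal_gyrus_left,left,DMN
anterior_parahippocampal_gyrus_right,right,DMN
posterior_parahippocampal_gyrus_left,left,DMN
posterior_parahippocampal_gyrus_right,right,DMN
anterior_fusiform_left,left,DMN
anterior_fusiform_right,right,DMN
posterior_fusiform_left,left,DMN
posterior_fusiform_right,right,DMN
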
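component,stage,VIA_VILI,TCT,HPV
propaganda,propaganda,51562.4,51562.4,51562.4
labor_drawing_materials,initial,12399.6,4145.1,4100.0
consumables_drawing_materials,initial,5284.1,5088.2,5032.9
instruments_drawing_materials,initial,446.4,448.2,443.3
tct_reading,initial,,23048.4,
hpv_detection,initial,,,13238.9
workforce_productivity_loss_initial,initial,5252.8,2157.4,2063.6
colposcopy,confirmation,13459.6,4352.9,5363.6
pathological_examination,confirmation,23908.0,6393.3,8062.0
via_vili_triage,confirmation,,,877.1
tct_triage,confirmation,,,1647.3
workforce_productivity_loss_confirmation,confirmation,6237.7,2016.7,7175.7
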
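reason,drg_code
respiratory_complication,04M052
pleural_effusion,04M132
reintervention,04C052
cardiac,05M092
other,23M062
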
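# Two-segment alternating Ri/Pis acquisition for the caffeoylquinic acid
# isomers on the fast (short-column) gradient: segment 1 monitors the
# mono-acyl isomers (precursor 353), segment 2 the di-acyl isomers
# (precursor 515). Each segment alternates a low-ExA reference-ion event
# with a high-ExA product-ion event.
segments:
  - segment_id: 1
    rt_window: [0.0, 3.0]
    precursor_mz: 353
    ri_event: {scan_range: [300, 365], exa: 15}
    pis_event: {scan_range: [95, 250], exa: 25}
    isolation_width: 3
    q_value: 0.25
    excitation_time: 50
  - segment_id: 2
    rt_window: [3.0, 7.5]
    precursor_mz: 515
    ri_event: {scan_range: [450, 530], exa: 10}
    pis_event: {scan_range: [140, 365], exa: 30}
    isolation_width: 3
    q_value: 0.25
    excitation_time: 50
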
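group,reference_mz,product_mz,isomer,ratio,sd
CQAs,353,191,3-CQA,0.23,0.01
CQAs,353,191,5-CQA,0.30,0.01
CQAs,353,191,4-CQA,0.02,0.01
CQAs,353,179,3-CQA,0.20,0.01
CQAs,353,179,5-CQA,0.02,0.01
CQAs,353,179,4-CQA,0.20,0.01
CQAs,353,173,3-CQA,0.01,0.01
CQAs,353,173,5-CQA,0.01,0.01
CQAs,353,173,4-CQA,0.17,0.01
CQAs,353,135,3-CQA,0.02,0.01
CQAs,353,135,5-CQA,0.01,0.01
CQAs,353,135,4-CQA,0.01,0.01
diCQAs,515,353,"3,4-diCQA",0.28,0.01
diCQAs,515,353,"3,5-diCQA",0.37,0.01
diCQAs,515,353,"4,5-diCQA",0.26,0.01
diCQAs,515,335,"3,4-diCQA",0.02,0.01
diCQAs,515,335,"3,5-diCQA",0.01,0.01
diCQAs,515,335,"4,5-diCQA",0.01,0.01
diCQAs,515,317,"3,4-diCQA",0.01,0.01
diCQAs,515,317,"3,5-diCQA",0.01,0.01
diCQAs,515,317,"4,5-diCQA",0.02,0.01
diCQAs,515,299,"3,4-diCQA",0.02,0.01
diCQAs,515,299,"3,5-diCQA",0.01,0.01
diCQAs,515,299,"4,5-diCQA",0.04,0.01
diCQAs,515,203,"3,4-diCQA",0.02,0.01
diCQAs,515,203,"3,5-diCQA",0.01,0.01
diCQAs,515,203,"4,5-diCQA",0.04,0.01
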
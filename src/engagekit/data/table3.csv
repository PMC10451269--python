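child,task,time_s,n_frames,task_epm_percent,overall_epm_percent,therapist_rate_percent
C1-ASD,1,19,186,65,84,88
C1-ASD,2,8,84,88,84,88
C1-ASD,3,19,187,98,84,88
C2-ASD,1,10,95,2,14,29
C2-ASD,2,11,108,14,14,29
C2-ASD,3,20,199,24,14,29
C3-ASD,1,12,124,52,41,42
C3-ASD,2,11,114,0,41,42
C3-ASD,3,2,25,72,41,42
C4-ASD,1,5,45,7,15,21
C4-ASD,2,5,45,22,15,21
C4-ASD,3,5,52,16,15,21
C5-ASD,1,19,187,0,9,42
C5-ASD,2,11,107,28,9,42
C5-ASD,3,19,187,0,9,42
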
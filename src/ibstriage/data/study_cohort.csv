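sample_id,classification,subtype,sex,age
IBS-006,control,none,F,55
IBS-011,control,none,F,50
IBS-012,control,none,F,50
IBS-016,control,none,F,52
IBS-017,control,none,F,57
IBS-021,control,none,F,49
IBS-022,control,none,F,60
IBS-032,control,none,F,50
IBS-043,control,none,F,54
IBS-045,control,none,F,50
IBS-046,control,none,F,51
IBS-056,control,none,F,51
IBS-010,control,none,M,54
IBS-019,control,none,M,50
IBS-020,control,none,M,47
IBS-026,control,none,M,53
IBS-027,control,none,M,50
IBS-030,control,none,M,47
IBS-002,case,IBS-D,F,56
IBS-003,case,unknown,F,49
IBS-004,case,IBS-M,F,51
IBS-007,case,IBS-M,F,53
IBS-009,case,IBS-D,M,58
IBS-013,case,IBS-C,F,57
IBS-024,case,IBS-M,M,51
IBS-025,case,IBS-D,M,55
IBS-028,case,IBS-D,F,55
IBS-033,case,IBS-M,F,46
IBS-034,case,IBS-M,F,41
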
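molecule_id,exp_conc_mg_ml,exp_visc_cp,acsins_pred_expconc_cp,dls_pred_expconc_cp,performance_expconc,acsins_pred_150_cp,dls_pred_150_cp,performance_150
V1,154,25.9,11.5,23.6,TRUE,10.4,21.0,TRUE
V2,143,34.2,12.8,17.5,FALSE_POSITIVE,15.7,21.6,TRUE
V3,159,13.4,20.0,24.1,FALSE_NEGATIVE,15.6,18.7,TRUE
V4,158,10.6,19.9,14.5,TRUE,15.9,11.7,TRUE
V5,152,8.1,14.3,12.7,TRUE,13.6,12.0,TRUE
V6,154,9.1,14.6,14.6,TRUE,13.1,13.1,TRUE
V7,165,42.5,22.1,21.8,TRUE,14.7,14.5,FALSE_POSITIVE
V8,144,10.5,12.6,10.2,TRUE,15.0,12.1,TRUE
V9,135,42.1,9.8,12.1,FALSE_POSITIVE,15.4,19.1,FALSE_POSITIVE
V10,153,9.9,14.5,12.6,TRUE,13.4,11.6,TRUE
V11,157,20.1,19.2,17.7,FALSE_POSITIVE,15.8,14.6,FALSE_POSITIVE
V12,157,13.8,18.2,11.3,TRUE,15.0,9.4,TRUE
V13,156,15,17.8,15.9,TRUE,15.1,13.5,TRUE
V14,150,10,15.6,13.0,TRUE,15.6,13.0,TRUE
V15,142,30.1,10.4,17.1,FALSE_POSITIVE,13.1,21.8,TRUE
V16,160,10.9,15.5,17.5,TRUE,11.9,13.3,TRUE
V17,152,9.1,15.2,11.4,TRUE,14.4,10.8,TRUE
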
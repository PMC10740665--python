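molecule_id,exp_visc_150_cp,acsins_pred_150_cp,dls_pred_150_cp,performance
Te1,16.5,15.5,17.8,TRUE
Te2,44,15.6,19.3,FALSE_POSITIVE
Te3,8.8,15.8,10.4,TRUE
Te4,49.3,15.2,14.4,FALSE_POSITIVE
Te5,7.9,8.3,8.4,TRUE
Te6,9.7,9.0,15.8,TRUE
Te7,13.1,10.7,14.7,TRUE
Te8,10.1,7.8,14.8,TRUE
Te9,13.9,12.1,15.2,TRUE
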
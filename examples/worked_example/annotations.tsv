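sample_id	group
S01	responder
S02	responder
S03	responder
S04	responder
S05	responder
S06	responder
S07	non_responder
S08	non_responder
S09	non_responder
S10	non_responder
S11	non_responder
S12	non_responder
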
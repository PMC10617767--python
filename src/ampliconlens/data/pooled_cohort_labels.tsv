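sample	response
TUM004	responder
TUM006	responder
TUM009	responder
TUM010	responder
H1581	responder
DMS114	responder
PDX003	responder
PDX006	responder
PDX008	responder
TUM001	nonresponder
TUM002	nonresponder
TUM003	nonresponder
TUM005	nonresponder
TUM007	nonresponder
TUM008	nonresponder
CL001	nonresponder
PDX001	nonresponder
PDX002	nonresponder
PDX004	nonresponder
PDX005	nonresponder
PDX007	nonresponder
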
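TC,mG,CS,GB,VN,Ph,Od,Ta,printed_class_error
mG,341,0,4,0,4,2,0,0.028
CS,1,45,1,0,1,0,0,0.062
GB,7,0,201,0,0,0,0,0.033
VN,1,1,0,311,27,3,1,0.096
Ph,14,0,0,24,351,2,1,0.104
Od,4,0,0,6,25,67,0,0.343
Ta,1,0,0,0,0,0,64,0.015
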
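TC,mG,CS,GB,VN,Ph,Od,Ta,printed_class_error
mG,338,0,5,2,4,2,0,0.037
CS,2,43,1,0,2,0,0,0.104
GB,7,0,201,0,0,0,0,0.033
VN,3,0,0,304,33,4,0,0.116
Ph,14,0,2,25,349,2,0,0.109
Od,4,0,0,7,27,64,0,0.372
Ta,1,0,0,0,0,0,64,0.015
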
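TC,mG,CS,GB,VN,Ph,Od,Ta,printed_class_error
mG,331,0,5,3,9,3,0,0.057
CS,1,43,1,1,2,0,0,0.104
GB,6,0,200,1,1,0,0,0.038
VN,8,0,1,296,34,5,0,0.139
Ph,11,0,2,35,341,3,0,0.130
Od,1,1,1,8,31,60,0,0.411
Ta,2,0,0,0,3,0,60,0.077
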
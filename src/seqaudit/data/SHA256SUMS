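f2d39f4e479ae27299795baaa3a4f34af72ff73d2a03d48dcedf87f4f5dbea96  confusion_aac.csv
d0fcafddacee3d9feb21d0f0d636c979022ae0493b5b287d2858e0f903ffd1d4  confusion_sez.csv
57ca540ce14f082d9fd70459f658af7f1eca6d300b755719d1e6dcef768d2c2a  confusion_dav.csv
6b6364c8012dc29b2ae5bc64a6b94c6cf7c32c2a22e50c5ebc45e7da4e1fae2b  overall_accuracy.csv
5321f13bb9354a79db7e63f005d609a70eb78fe83484a8c913bb1ad359221025  shortlist_votes.csv
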
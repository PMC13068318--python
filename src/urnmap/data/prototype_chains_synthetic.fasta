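;; Synthetic stand-in groove-chain sequences (NOT real HLA-II chains).
>alpha_synthetic
CSNGILFHTNKYDWKLQMWFFINQEIMDQPHGYRNVEKGVANPVYTVIFYARDEELVKFDIAGVSLLSGVIENKEAMMLSYFKWAIGEVQVSDPW
>beta_synthetic
INPQVPFLVHCRMCARGLIVPKRFELAQVPQKVAFFPEYVPTYEGQSKLKFPDCFWRFKGRHYRDHTHFNADRCHIPALIADIKITSIMYIIHLG
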
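unit,taxon,nisp,mni,habitat,rank,determined
A2-A1,Bos/Bison sp.,3,2,plain,high,1
A2-A1,Capra ibex,136,9,mountain,high,1
A2-A1,Rupicapra rupicapra,54,4,mountain,low,1
A2-A1,Megaloceros giganteus,8,2,plain,high,1
A2-A1,Cervus elaphus,44,5,plain,high,1
A2-A1,Capreolus capreolus,18,2,plain,low,1
D3,Bos/Bison sp.,1,1,plain,high,1
D3,Capra ibex,27,4,mountain,high,1
D3,Rupicapra rupicapra,30,5,mountain,low,1
D3,Megaloceros giganteus,4,1,plain,high,1
D3,Cervus elaphus,10,1,plain,high,1
D3,Capreolus capreolus,7,3,plain,low,1
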
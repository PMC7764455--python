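tag,threshold,items
F1,0.40,fruit;juice;salad;vegetables;chips;beans;fiber;wholebread;cheese;cakes;cream;grains;pizza;nuts_salt;nuts;potato;readmeat;whitemeat;fish
F2,0.30,fruit;juice;salad;vegetables;chips;beans;fiber;wholebread;cheese;cakes;grains;nuts;potato;readmeat;whitemeat;fish
F3,0.25,fruit;juice;salad;beans;fiber;wholebread;grains;nuts;readmeat;whitemeat
F4,0.20,fruit;juice;salad;fiber;wholebread;grains
F5,0.10,fruit;juice
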
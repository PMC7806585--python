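{
  "characteristic_tree_v1.csv": "eae125a7cd2d05a430c409ee3a8dd430f5b380eac5bafabd8c61dc524e446b22",
  "upper_airway_sections_v1.csv": "53bf1101b30a63022c4104ac642b745a4a4cbca1ab573ea96397c829a8ed97ef"
}
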
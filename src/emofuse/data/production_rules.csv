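face_state,eeg_intensity,result
happiness,strong,happiness
happiness,moderate,happiness
happiness,weak,neutral
neutral,strong,happiness
neutral,moderate,neutral
neutral,weak,neutral
sadness,strong,fear
sadness,moderate,sadness
sadness,weak,sadness
fear,strong,fear
fear,moderate,fear
fear,weak,sadness
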
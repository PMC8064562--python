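species,group
Salicornia persica,S. europaea complex
Salicornia europea,S. europaea complex
Salicornia patula,S. europaea complex
Salicornia brachiate,S. europaea complex
Salicornia herbacea,S. europaea complex
Salicornia maritime,S. europaea complex
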
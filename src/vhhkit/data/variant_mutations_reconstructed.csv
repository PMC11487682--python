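variant_id,mutations
VHH1-v1.0,
VHH1-v1.1,Q1E;L12V;A15P
VHH1-v1.2,Q1E;L12V;A15P;A84P
VHH1-v1.3,Q1E;L12V;A15P;A84P;F78I
VHH1-v1.4,Q1E;L12V;A15P;A84P;V87L
VHH1-v1.5,Q1E;L12V;A15P;A84P;V87L;F78I
VHH1-v1.6,Q1E;L12V;A15P;A84P;V87L;E49G;H50L
VHH1-v1.7,Q1E;L12V;A15P;A84P;V87L;E49G
VHH1-v1.8,Q1E;L12V;A15P;A84P;V87L;E49G;H50L;F78I
VHH1-v1.9,Q1E;L12V;A15P;A84P;V87L;E49G;H50L;F78I;V2L
VHH1-v1.10,Q1E;L12V;A15P;A84P;V87L;E49G;H50L;F78I;V2L;G52W
VHH2-v1.0,
VHH2-v1.1,Q1E;V5L;L12V;A15P
VHH2-v1.2,Q1E;V5L;L12V;A15P;A84P;K89Q
VHH2-v1.3,Q1E;V5L;L12V;A15P;A84P;K89Q;V87L
VHH2-v1.4,Q1E;V5L;L12V;A15P;A84P;K89Q;F42V
VHH2-v1.5,Q1E;V5L;L12V;A15P;A84P;K89Q;A49G;R50L
VHH2-v1.6,Q1E;V5L;L12V;A15P;A84P;K89Q;A49G;R50L;F42V
VHH2-v1.7,Q1E;V5L;L12V;A15P;A84P;K89Q;A49G;R50L;F78I
VHH2-v1.8,Q1E;V5L;L12V;A15P;A84P;K89Q;A49G;R50L;F78I;S52W
VHH2-v1.9,Q1E;V5L;L12V;A15P;A84P;K89Q;A49G;R50L;F78I;F42V
VHH2-v1.10,Q1E;V5L;L12V;A15P;A84P;K89Q;A49G;R50L;F78I;S52W;F42V
VHH2-v1.11,Q1E;V5L;L12V;A15P;A84P;K89Q;A49G;R50L;V25A
VHH2-v1.12,Q1E;V5L;L12V;A15P;A84P;K89Q;A49G;R50L;V25A;S52W
VHH2-v1.13,Q1E;V5L;L12V;A15P;A84P;K89Q;A49G;R50L;V25A;F42V
VHH2-v1.14,Q1E;V5L;L12V;A15P;A84P;K89Q;A49G;R50L;V25A;S52W;F42V
VHH2-v1.15,Q1E;V5L;L12V;A15P;A84P;K89Q;A49G;R50L;V25A;V87L
VHH2-v1.16,Q1E;V5L;L12V;A15P;A84P;K89Q;A49G;R50L;V25A;V87L;S52W
VHH2-v1.17,Q1E;V5L;L12V;A15P;A84P;K89Q;A49G;R50L;V25A;V87L;F42V
VHH2-v1.18,Q1E;V5L;L12V;A15P;A84P;K89Q;A49G;R50L;V25A;V87L;S52W;F42V
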
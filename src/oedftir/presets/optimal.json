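{
 "smoothing": "sg",
 "sg_window": 15,
 "sg_polyorder": 2,
 "baseline": "sg_diff",
 "diff_window": 15,
 "diff_polyorder": 2,
 "diff_order": 1,
 "normalization": "vector",
 "scaling": "none",
 "feature_extraction": "pca",
 "feature_variance": 90.0,
 "classifier": "lda"
}
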
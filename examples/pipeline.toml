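# Full pipeline on a synthetic session: simulate -> preprocess -> features ->
# contrast -> fusion ablation, all six classifiers, 5-fold CV.
seed = 1
out_dir = "neurofuse_out"
mode = "simulate"

[preprocess]
eeg_band = [0.5, 50.0]
fnirs_band = [0.01, 0.1]
filter_order = 4
epoch_window = [5.0, 205.0]
baseline_s = 10.0

[features]
window_s = 1.0
glm_context_s = 20.0
hrf = "none"
glm_design = "sliding"

[fusion]
relieff = { k = 10, m = "all", threshold = 0.0 }

[classify]
classifiers = ["svm", "knn", "random_forest", "adaboost", "naive_bayes", "dac"]
folds = 5
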
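"""Train the deep models (CNN, CNN+SVM hybrid, LSTM, stacked AE + SVM) on
raw gaze windows of a reduced study.

Windows are decimated for CPU-scale training; the printed accuracies are
out-of-fold under 3-fold stratified cross-validation.
"""

import gazeload as gl
from gazeload.classifiers import CVScheme
from gazeload.deep import (
    AEConfig, CNNConfig, LSTMConfig,
    ae_svm_hybrid, cnn_svm_hybrid, prepare_raw_windows, train_cnn, train_lstm,
)

segments = gl.simulate_study(gl.GazeSimSpec(n_subjects=10, seed=2))
cv = CVScheme(k=3, seed=2)
data = prepare_raw_windows(segments, fs=30.0, window_s=30.0, target_len=120)
lstm_data = prepare_raw_windows(segments, fs=30.0, window_s=30.0, target_len=60)
flat = prepare_raw_windows(segments, fs=30.0, window_s=30.0, flatten=True, target_len=120)
print(f"{len(data)} raw windows, channeled {data.X.shape}, flattened {flat.X.shape}")

cnn, preds = train_cnn(data.X, data.y, CNNConfig(epochs=10, seed=2), cv)
print(f"CNN ({cnn.n_layers} layers)        accuracy {preds.accuracy:.3f}")
hybrid = cnn_svm_hybrid(cnn, data.X, data.y, cv)
print(f"CNN+SVM (FC features)  accuracy {hybrid.accuracy:.3f}")
_, lpreds = train_lstm(lstm_data.X, lstm_data.y, LSTMConfig(hidden_units=32, epochs=15, seed=2), cv)
print(f"LSTM (5 layers)        accuracy {lpreds.accuracy:.3f}")
apreds = ae_svm_hybrid(flat.X, flat.y, AEConfig(epochs=150, seed=2), cv)
print(f"AE(100->50)+SVM        accuracy {apreds.accuracy:.3f}")
print("\nThe networks learn the class contrast directly from raw (x, y) "
      "windows, without the hand-crafted 13-feature stage.")
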
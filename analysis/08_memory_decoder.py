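"""Verbal-memory decoding: offline base training plus the online
transfer-learning replay.

Trains the branch CNN1D+LSTM decoder on a synthetic memory session with an
onset-locked theta effect, then replays the online protocol: the dense
head is retrained block by block on an accumulating pool (branch
parameters frozen) and the remaining blocks are scored as the prediction
phase.  Writes results/decoder_report.json.
"""

import json
from pathlib import Path

import numpy as np

from neurostack import synth
from neurostack.decoder import (
    balance_classes,
    decode_metrics,
    extract_windows,
    split_by_block,
    transfer_and_predict,
)
from neurostack.decoder.model import BranchDecoder, DecoderSpec
from neurostack.decoder.pipeline import _stratified_folds

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SPEC = DecoderSpec(strides=(4, 4), pool=4, epochs=30, batch_size=8)


def main() -> None:
    seed = 0
    rec, events, _ = synth.gen_memory_session(
        n_blocks=20, words_per_block=10, p_remember=0.5, theta_effect=2.0,
        n_channels=4, n_regions=2, seed=seed,
    )
    ds = balance_classes(extract_windows(rec, events), seed=seed)

    # offline base model: stratified half split
    test_idx, train_idx = _stratified_folds(ds.labels, 2, seed)
    model = BranchDecoder(ds.channels_per_region(), SPEC, seed=seed)
    model.fit(ds.chunks[train_idx], ds.labels[train_idx].astype(float),
              seed=seed)
    offline = decode_metrics(model.predict_proba(ds.chunks[test_idx]),
                             ds.labels[test_idx])

    # online replay on a fresh session: 5 training + 4 prediction blocks
    rec2, events2, _ = synth.gen_memory_session(
        n_blocks=9, words_per_block=10, p_remember=0.5, theta_effect=2.0,
        n_channels=4, n_regions=2, seed=seed + 100,
    )
    blocks = split_by_block(extract_windows(rec2, events2))
    online = transfer_and_predict(model, blocks, n_train_blocks=5,
                                  epochs_per_block=10, seed=seed)

    report = {
        "offline": {"f1": offline.f1, "accuracy": offline.accuracy,
                    "auc": offline.auc, "n_test_events": int(len(test_idx))},
        "online": {"f1": online.f1, "accuracy": online.accuracy,
                   "auc": online.auc,
                   "n_prediction_events": int(online.labels.size)},
    }
    (OUT / "decoder_report.json").write_text(json.dumps(report, indent=1))
    print(json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
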
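#!/usr/bin/env python
"""External validation of the three published models from their printed
predictions.

For each model (similarity-field steric+acceptor, donor+acceptor, and the
2D descriptor equation) recomputes r2pred = (SD − PRESS)/SD over the six
test compounds about the 19-compound training mean, and the through-origin
criterion battery (r0², r0'², k, k').  Writes
results/external_validation.json.
"""

import json
from pathlib import Path

from comsiakit import r2pred, tropsha_report
from comsiakit.datasets import load_model_predictions

OUT = Path(__file__).resolve().parents[1] / "results"

MODELS = [
    ("steric_acceptor", "pred_steric_acceptor", 0.639),
    ("donor_acceptor", "pred_donor_acceptor", 0.626),
    ("hansch_2d", "pred_2d", 0.607),
]


def main():
    OUT.mkdir(exist_ok=True)
    df = load_model_predictions()
    test = df[df["role"] == "test"]
    train_mean = df.loc[df["role"] == "train", "actual"].mean()

    payload = {}
    for label, col, q2 in MODELS:
        rp, sd, press = r2pred(test["actual"], test[col], train_mean)
        rep = tropsha_report(test["actual"], test[col], q2_train=q2)
        payload[label] = {"r2pred": round(rp, 4), "SD": round(sd, 4),
                          "PRESS": round(press, 4),
                          **json.loads(rep.to_json())}
        print(f"{label}: r2pred = {rp:.4f}, external criteria "
              f"{'all pass' if rep.all_pass else 'FAIL'}")
    (OUT / "external_validation.json").write_text(json.dumps(payload, indent=2))
    print(f"wrote {OUT / 'external_validation.json'}")


if __name__ == "__main__":
    main()
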
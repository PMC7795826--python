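#!/usr/bin/env python
"""Parameter-recovery experiment on synthetic cohorts.

Finding: with the default two-point truth (98% of patients carrying mPM on
300 of 4000 sub-surfaces), 200 replicate 26-patient cohorts recover a mean
residual-disease probability within a few percent of the truth; the
estimator saturates near 1 whenever any positive biopsy is observed, so
its error is dominated by a small upward bias rather than variance.
"""

import argparse
import json
from pathlib import Path

from mpmburden import SyntheticConfig, recovery_experiment, summarize_recovery

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=2024)
    parser.add_argument("--replicates", type=int, default=200)
    args = parser.parse_args()

    cfg = SyntheticConfig(seed=args.seed)
    report = recovery_experiment(cfg, n_replicates=args.replicates)
    summary = summarize_recovery(report)
    print(f"truth P(K >= 1) = {summary['truth']:.3f}")
    print(f"mean estimate   = {summary['mean_estimate']:.3f}")
    print(f"bias            = {summary['bias']:+.4f}")
    print(f"rmse            = {summary['rmse']:.4f}")
    print(f"failures        = {summary['n_failed']}/{summary['n_replicates']}")

    OUT.mkdir(exist_ok=True)
    report.to_csv(OUT / "recovery.csv", index=False)
    (OUT / "recovery_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"wrote {OUT / 'recovery.csv'} and {OUT / 'recovery_summary.json'}")


if __name__ == "__main__":
    main()
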
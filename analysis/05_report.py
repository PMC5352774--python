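"""Render the descriptive report for a scenario.

Scatter-panel grids (WMC x RT quantiles, accuracy x RT quantiles, each
annotated with its default-prior slope Bayes factor), posterior-density
figures, and the Bayes-factor summary table, written under
results/report_<scenario>/.
"""

import argparse
from pathlib import Path

from wprdm.data_io import BlindingRecord, load_tables, unblind
from wprdm.pipeline import AnalysisConfig, render_report, run_confirmatory
from wprdm.wpr_inference import MCMCConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scenario", default="wpr_true")
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    d = args.data / args.scenario
    trials, wmc_blinded = load_tables(d / "trials.csv", d / "wmc_blinded.csv")
    wmc = unblind(wmc_blinded, BlindingRecord.from_json(d / "blinding_record.json"))

    config = AnalysisConfig(
        seed=args.seed, run_h3=False, run_h4=False, wpr_mcmc=MCMCConfig()
    )
    bundle = run_confirmatory(config, trials=trials, wmc=wmc)
    files = render_report(bundle, args.out / f"report_{args.scenario}")
    print("\n".join(files))


if __name__ == "__main__":
    main()
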
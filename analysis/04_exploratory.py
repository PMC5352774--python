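"""Exploratory variants on the unblinded data.

Reruns the WPR test with the negativity constraints released, repeats it
inside ten homogeneous-caution subgroups (cut at the deciles of the joint
diffusion fit's boundary-separation estimates), and splits the sample into
students and non-students.  Requires 03_confirmatory.py's unblinded stage
(rerun here to obtain the in-memory bundle and boundary estimates).
"""

import argparse
from pathlib import Path

from wprdm.data_io import BlindingRecord, load_tables, unblind
from wprdm.diffusion_inference import DiffusionMCMCConfig
from wprdm.pipeline import AnalysisConfig, run_confirmatory, run_exploratory
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
    record = BlindingRecord.from_json(d / "blinding_record.json")
    wmc = unblind(wmc_blinded, record)

    config = AnalysisConfig(
        seed=args.seed,
        run_h1=False, run_h2=False, run_h3=False, run_h4=True,
        wpr_mcmc=MCMCConfig(),
        diffusion_mcmc=DiffusionMCMCConfig(chains=2, warmup=500, draws=800,
                                           rhat_threshold=1.1),
    )
    confirmatory = run_confirmatory(config, trials=trials, wmc=wmc)
    bundle = run_exploratory(config, confirmatory)
    out = args.out / f"exploratory_{args.scenario}.json"
    args.out.mkdir(parents=True, exist_ok=True)
    bundle.to_json(out)
    print(f"exploratory results -> {out}")
    for label in ("h1a_star", "h1b_star"):
        summ = bundle.results[label]
        print(f"  {label} (constraints released): BF01 = {summ['bf01']:.3g}, "
              f"slope mean = {summ['beta1_mean']:.3f}")
    caution = bundle.results["caution_subgroups"]
    print(f"  caution subgroups fitted: {len(caution['table'])} "
          f"({len(caution['warnings'])} warnings)")
    split = bundle.results["student_split"]
    print(f"  students {split.get('n_students')} / non-students "
          f"{split.get('n_non_students')} / flag missing "
          f"{split.get('n_missing_student_flag')}")


if __name__ == "__main__":
    main()
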
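"""Run the frozen confirmatory pipeline: blinded stage, then unblinded.

For the chosen scenario this executes the fixed stage order
(preprocess -> quantile curves -> H1a/H1b/H2 -> hierarchical diffusion
H3a/H3b -> joint diffusion H4) twice: first against the shuffled key
variable (all Bayes factors flagged meaningless), then after unblinding.
Summaries land in results/confirmatory_<scenario>_{blinded,unblinded}.json.

The heavier diffusion stages (H3/H4) are on by default at desk scale; use
--skip-diffusion for a quick curve-only run.
"""

import argparse
import dataclasses
from pathlib import Path

from wprdm.data_io import BlindingRecord, load_tables, unblind
from wprdm.diffusion_inference import DiffusionMCMCConfig
from wprdm.pipeline import AnalysisConfig, run_confirmatory
from wprdm.wpr_inference import MCMCConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scenario", default="wpr_true")
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--skip-diffusion", action="store_true")
    args = ap.parse_args()

    d = args.data / args.scenario
    trials, wmc_blinded = load_tables(d / "trials.csv", d / "wmc_blinded.csv")
    record = BlindingRecord.from_json(d / "blinding_record.json")

    config = AnalysisConfig(
        blinding="blinded",
        seed=args.seed,
        run_h3=not args.skip_diffusion,
        run_h4=not args.skip_diffusion,
        wpr_mcmc=MCMCConfig(),
        diffusion_mcmc=DiffusionMCMCConfig(chains=2, warmup=500, draws=800,
                                           rhat_threshold=1.1),
    )
    args.out.mkdir(parents=True, exist_ok=True)

    bundle = run_confirmatory(config, trials=trials, wmc=wmc_blinded,
                              blinding_record=record)
    out_b = args.out / f"confirmatory_{args.scenario}_blinded.json"
    bundle.to_json(out_b)
    print(f"stage one (blinded key) -> {out_b}")
    for label, summ in sorted(bundle.results.items()):
        if "bf01" in summ:
            print(f"  {label}: BF01 = {summ['bf01']:.3g}  [meaningless by construction]")

    # stage two: unblind and rerun the identical frozen pipeline
    wmc_true = unblind(wmc_blinded, record)
    config_u = dataclasses.replace(config, blinding="unblinded")
    bundle_u = run_confirmatory(config_u, trials=trials, wmc=wmc_true)
    out_u = args.out / f"confirmatory_{args.scenario}_unblinded.json"
    bundle_u.to_json(out_u)
    if bundle_u.boundary_estimates is not None:
        bundle_u.boundary_estimates.to_csv(
            args.out / f"boundary_estimates_{args.scenario}.csv", index=False
        )
    print(f"stage two (unblinded) -> {out_u}")
    for label, summ in sorted(bundle_u.results.items()):
        if "bf01" in summ:
            print(f"  {label}: BF01 = {summ['bf01']:.3g}")


if __name__ == "__main__":
    main()
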
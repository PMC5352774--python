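"""Generate the three scenario datasets the analyses run on.

Writes, for each scenario (wpr_true, caution_confound, null), a trial table,
a WMC table and the generating ground truth under results/data/<scenario>/.
The default size here is a desk-scale 200 participants; pass --full for the
916-participant study size.
"""

import argparse
from pathlib import Path

from wprdm.data_io import write_tables
from wprdm.synthetic_data import (
    SCENARIO_PRESETS,
    apply_contamination_and_censoring,
    generate_population,
    scenario_config,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--full", action="store_true",
                    help="use the full 916-participant study size")
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    overrides = {} if args.full else {"n_participants": 200}
    for name in SCENARIO_PRESETS:
        cfg = scenario_config(name, seed=args.seed, **overrides)
        trials, wmc, truth = generate_population(cfg)
        trials = apply_contamination_and_censoring(trials, cfg)
        out = args.out / name
        out.mkdir(parents=True, exist_ok=True)
        write_tables(trials, wmc, out / "trials.csv", out / "wmc.csv")
        truth.participants.to_csv(out / "truth.csv", index=False)
        n_cens = int(trials["censored"].sum())
        print(
            f"{name}: {cfg.n_participants} participants, {len(trials)} trials "
            f"({n_cens} censored at {cfg.rt_cutoff} s) -> {out}/"
        )


if __name__ == "__main__":
    main()
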
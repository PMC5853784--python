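"""Generate the synthetic survey: spectra + traits for 60 genotypes x 4
repetitions (with detector-jump artifacts on), plus 80 A-Ci curves.

Writes results/data/{spectra.csv,traits.csv} and results/data/aci_truth.csv.
"""

from pathlib import Path

import pandas as pd

import leafspec as ls

SEED = 2017
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = ls.GeneratorConfig(seed=SEED, add_jumps=True)
    records, traits, truth = ls.generate_dataset(cfg)
    ls.write_spectra(records, OUT / "spectra.csv", dialect="wide")
    ls.write_trait_table(traits, OUT / "traits.csv")
    print(f"simulated {len(records)} records ({cfg.n_genotypes} genotypes x {cfg.repetitions} reps)")
    print(f"trait ranges: " + ", ".join(f"{t}={lo}-{hi}" for t, (lo, hi) in cfg.trait_ranges.items()))

    aci_cfg = ls.ACiSetConfig(n_curves=80, seed=SEED)
    curves, truths = ls.generate_aci_set(aci_cfg)
    rows = []
    for c, t in zip(curves, truths):
        for ci, a in zip(c.ci, c.a):
            rows.append({"record_id": c.record_id, "ci": ci, "a": a, "tleaf": c.tleaf_c, "qin": 1800.0})
    pd.DataFrame(rows).to_csv(OUT / "aci_curves.csv", index=False)
    pd.DataFrame(
        [{"record_id": c.record_id, "Vcmax": t.Vcmax, "Vcmax25": t.Vcmax25, "J": t.J, "Rd": t.Rd, "Tleaf": t.Tleaf}
         for c, t in zip(curves, truths)]
    ).to_csv(OUT / "aci_truth.csv", index=False)
    print(f"simulated {len(curves)} A-Ci curves (noise sd {aci_cfg.noise_sd} umol m-2 s-1)")


if __name__ == "__main__":
    main()
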
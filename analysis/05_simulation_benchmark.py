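#!/usr/bin/env python
"""Zygosity-recovery benchmark on synthetic pileups with known truth.

Two regimes:
  * default noise — beta-binomial fractions centered at the cohort's
    empirical means (0.72 hom / 0.38 het), depths log-uniform 50-2000x;
  * clean — well-separated centers at depth >= 500, where recovery should
    be perfect.

Writes results/simulation_benchmark.json.
"""

import json
from pathlib import Path

import numpy as np

from pahscreen.genotyping import derive_threshold, pileup_call
from pahscreen.simulate import SimulationConfig, simulate_cohort, simulate_pileup

OUT = Path(__file__).resolve().parent.parent / "results"
N_PILEUPS = 3000
N_PATIENTS = 200


def recovery(config: SimulationConfig, seed: int, min_depth: int = 1) -> dict:
    rng = np.random.default_rng(seed)
    obs = [
        simulate_pileup("hom" if i % 3 == 0 else "het", config, rng)
        for i in range(N_PILEUPS)
    ]
    res = pileup_call(obs, min_depth=min_depth, min_af=0.0)
    kept = [o for o in obs if o.depth >= min_depth]
    correct = sum(z == o.true_zygosity for z, o in zip(res.zygosities, kept))
    return {
        "n": len(kept),
        "recovery_rate": correct / len(kept),
        "dropped": len(res.dropped),
    }


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    default = recovery(SimulationConfig(seed=4), seed=4)
    clean = recovery(
        SimulationConfig(
            depth_min=500, af_center_hom=0.90, af_center_het=0.30,
            af_concentration=200, seed=3,
        ),
        seed=3,
    )

    syn = simulate_cohort(N_PATIENTS, config=SimulationConfig(
        depth_min=500, af_center_hom=0.90, af_center_het=0.30,
        af_concentration=200, seed=11), seed=11)
    t = derive_threshold(syn)
    errors = sum(
        1
        for rec in syn
        for call, truth in zip(rec.calls, rec.truth_zygosity)
        if ("hom" if call.allele_fraction >= t else "het") != truth
    )

    payload = {
        "default_noise": default,
        "clean_high_depth": clean,
        "threshold_recovery": {
            "n_patients": N_PATIENTS,
            "derived_threshold": t,
            "misclassified_calls": errors,
        },
    }
    (OUT / "simulation_benchmark.json").write_text(
        json.dumps(payload, indent=2) + "\n"
    )
    print(f"default noise: {default['recovery_rate']:.3f} of "
          f"{default['n']} calls recover true zygosity at the 0.58 cutoff")
    print(f"clean regime (depth>=500, separated centers): "
          f"{clean['recovery_rate']:.3f}")
    print(f"threshold re-derived on a {N_PATIENTS}-patient synthetic cohort: "
          f"{t:g} ({errors} truth errors)")


if __name__ == "__main__":
    main()
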
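#!/usr/bin/env python
"""Profile-likelihood recovery of the headline demographic parameters.

Simulates a joint SFS at the best-fit scenario (divergences at 128.5 and
106.3 ka, admixed origins of NC at 13.5 ka with 81% N ancestry and of SE
at 8.2 ka with 37% SW ancestry) and profiles the composite likelihood
over each parameter in turn, holding the others at truth.  This is the
same computation as scripts/acceptance.py, at lighter settings, printing
a side-by-side table.  Writes results/recovery/profiles.json.
"""

import json
import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import numpy as np

from stepstone.coalescent import simulate_snp_sfs
from stepstone.inference import profile_likelihood
from stepstone.models import BEST_FIT_SE_NC_ADMIX, build_named_model

FIVE = ("SW", "SE", "C", "NC", "N")
OUT = Path(__file__).resolve().parent.parent / "results" / "recovery"

GRIDS = {
    "alpha_SE": np.linspace(0.05, 0.95, 19),
    "alpha_NC": np.linspace(0.05, 0.95, 19),
    "T1": np.geomspace(10_700.0, 45_000.0, 13),
    "T2": np.geomspace(1_400.0, 12_800.0, 13),
    "T3": np.geomspace(830.0, 10_600.0, 13),
    "T4": np.geomspace(110.0, 1_340.0, 13),
}


def main() -> None:
    samples = {k: 5 for k in FIVE}
    truth_model = build_named_model("model4_SE_NC_admix", BEST_FIT_SE_NC_ADMIX,
                                    samples=samples)
    obs = simulate_snp_sfs(truth_model, n_snps=5000, n_trees=3000, seed=31)

    profiles = {}
    print(f"{'parameter':10s} {'truth':>10s} {'recovered':>10s} {'rel err':>8s}")
    for focal, grid in GRIDS.items():
        t0 = time.time()
        prof = profile_likelihood("model4_SE_NC_admix", obs, focal, grid,
                                  BEST_FIT_SE_NC_ADMIX, n_sims=2000, seed=7)
        truth = BEST_FIT_SE_NC_ADMIX[focal]
        err = prof["argmax"] / truth - 1.0
        print(f"{focal:10s} {truth:10.4g} {prof['argmax']:10.4g} {err:+8.1%}"
              f"   ({time.time() - t0:.0f}s)")
        profiles[focal] = {
            "grid": prof["grid"].tolist(),
            "lnCL": prof["lnCL"].tolist(),
            "argmax": prof["argmax"],
            "truth": truth,
        }

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "profiles.json").write_text(json.dumps(profiles, indent=1, sort_keys=True))
    print(f"wrote {OUT / 'profiles.json'}")


if __name__ == "__main__":
    main()
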
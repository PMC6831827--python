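#!/usr/bin/env python
"""Rigid-body / flexible-linker refinement against SEC-SAXS data.

Simulates a SWING-like SEC-SAXS curve (from a hinge-bent conformer, to
give the refinement something real to find at low noise), then refines
the straight starting model with the evolutionary search: RH1 core and
coiled coil rigid, tag+N-terminus, hinge (67-77) and C-terminus free.
Writes the chi^2 traces and the refined model.

Finding: when the data carry a resolvable conformational signal the
search recovers the generating hinge bend and the best-so-far chi^2 trace
is monotone; at the realistic noise level of the default generator a
small (20 degree) bend is NOT resolvable -- the curve changes by <0.5%
-- so refinement is then a no-op within noise (see docs/methods.md).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from jiptandem import model_builder as mb
from jiptandem import refinement as rf
from jiptandem import synthetic_data as sd

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 2024


def main() -> None:
    model = mb.assemble_rh1_lzi_dimer(sd.fixture_construct())
    OUT.mkdir(exist_ok=True)
    mask = rf.FlexibilityMask()
    quiet = sd.NoiseModel(snr_at_qmin=5000.0, relative_floor=2e-4, seed=SEED)
    decoy = sd.make_decoys(model, bend_angles_deg=(60.0,))[0]
    data = sd.simulate_curve(decoy, noise=quiet)

    settings = rf.RefinementSettings(population=20, generations=30,
                                     mutation_deg=15.0, n_runs=3, seed=SEED)
    res = rf.refine_against_saxs(model, data, mask, settings)
    mb.write_pdb(res.best, OUT / "refined.pdb")
    pd.DataFrame({"generation": np.arange(len(res.trace)),
                  "best_chi2": res.trace}).to_csv(
        OUT / "chi2_trace.tsv", sep="\t", index=False)

    rows = [
        ("generating hinge bend (deg)", 60.0),
        ("chi^2 initial (straight model)", round(res.chi2_initial, 3)),
        ("chi^2 final (best of runs)", round(res.chi2_final, 3)),
        ("per-run final chi^2", [round(c, 3) for c in res.run_chi2]),
        ("recovered hinge angle (deg)", round(rf.hinge_angle(res.best), 1)),
        ("Rg of refined model (A)", round(res.rg_best, 1)),
    ]
    df = pd.DataFrame(rows, columns=["quantity", "value"])
    df.to_csv(OUT / "refinement_summary.tsv", sep="\t", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
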
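"""Validation experiments: oracle equivalence and statistical calibration.

Runs the same experiments as scripts/acceptance.py at reduced replicate
counts and writes a summary table under results/.
"""
import importlib.util
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "cfg00", Path(__file__).parent / "00_config.py"
)
cfg00 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg00)

from impactmodes import experiments as E

rows = []
dev = E.glm_oracle_deviation(n_fixtures=25, seed=0)
rows.append(("glm max |t - t_OLS|", dev, "should be ~1e-14"))
rate = E.fwe_null_rejection_rate(n_replicates=200, seed=0)
rows.append(("FWE rejection rate under null", rate, "should be ~0.05"))
spatial, loading = E.mode_recovery(n_seeds=3, seed=0)
rows.append(("mode spatial recovery mean |r|", spatial, "should be > 0.95"))
rows.append(("mode loading recovery mean |r|", loading, "should be > 0.90"))
va = E.variance_accounting(seed=0)
rows.append(("variance-explained abs error", va["fraction_error"], "should be < 0.02"))
pgs = E.pgs_validation(n_seeds=10, seed=0)
rows.append(("PGS-liability correlation", pgs["liability_r_mean"], "should be > 0"))
rows.append(("best-threshold selection rate", pgs["selection_rate"], "should be >= 0.9"))

table = pd.DataFrame(rows, columns=["experiment", "value", "expectation"])
out = cfg00.RESULTS / "validation.tsv"
out.parent.mkdir(parents=True, exist_ok=True)
table.to_csv(out, sep="\t", index=False)
print(table.to_string(index=False))
print(f"\nwritten to {out}")
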
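#!/usr/bin/env python
"""Parameter-recovery validation of each pipeline stage (reduced scale).

Runs the self-validation benchmarks at a size suited to an interactive
session — bleach-correction fidelity, kinetic recovery, block recovery,
statistical-layer oracles and motion correction — and writes one tidy table
under results/validation/. scripts/acceptance.py runs the same benchmarks
at full scale.
"""

from pathlib import Path

import pandas as pd

from gpcal import benchmarks

SEED = 1
OUT = Path("results/validation")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []

    b = benchmarks.bleach_correction_fidelity(SEED, n_traces=40)
    rows.append(("corrected RMS / noise floor (max)", b["rms_over_floor_max"], "<= 1.2"))
    rows.append(("false events per 10 bleach-only traces", b["false_events_per_10_traces"], "< 1"))

    k = benchmarks.kinetic_recovery(SEED, n_events=150)
    rows.append(("amplitude median |rel err| %", k["amplitude_median_abs_rel_err_pct"], "< 10"))
    rows.append(("FWHM median |rel err| %", k["fwhm_median_abs_rel_err_pct"], "< 15"))
    rows.append(("rise median |rel err| %", k["rise_median_abs_rel_err_pct"], "< 15"))
    rows.append(("decay median |rel err| %", k["decay_median_abs_rel_err_pct"], "< 15"))

    blk = benchmarks.block_quantification(SEED, 0.25, n_cells=120)
    rows.append(("median % remaining at 25% block", blk["median_pct_amplitude_remaining"], "25 +/- 10% rel"))
    rows.append(("duration-filter mismatches", blk["filter_mismatches"], "0"))

    mw = benchmarks.mann_whitney_exact_check(SEED, n_instances=10)
    rows.append(("Mann-Whitney exact vs enumeration (max |dp|)", mw["max_abs_p_diff"], "0"))
    ks = benchmarks.ks_oracle_check(SEED, n_instances=30)
    rows.append(("KS D vs sup-scan oracle (max |dD|)", ks["max_abs_d_diff"], "0"))

    m = benchmarks.motion_recovery(SEED, n_movies=2, n_frames=200)
    rows.append(("motion shifts recovered exactly (%)", m["exact_recovery_pct"], ">= 99"))

    table = pd.DataFrame(rows, columns=["check", "measured", "expectation"])
    table.to_csv(OUT / "validation.csv", index=False)
    print(table.to_string(index=False))
    print(f"table -> {OUT / 'validation.csv'}")


if __name__ == "__main__":
    main()
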
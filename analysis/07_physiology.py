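"""Worked physiology examples: tracer influx and qPCR quantification.

Demonstrates the closed-form calculations on representative numbers: the
unidirectional zinc influx J_in = cpm/(SA*bw*t) for a juvenile-zebrafish
scale measurement, and standard-curve qPCR quantification normalised to
the 18s rRNA reference.

Run standalone:  python analysis/07_physiology.py
"""

import numpy as np

from gillzinc import physiology


def main() -> None:
    # influx: 0.44 g fish, 3 h flux, water SA 12 cpm/pmol
    sa = physiology.specific_activity(label_cpm_per_l=6.0e7, total_zn_pmol_per_l=5.0e6)
    j_in = physiology.zinc_influx(cpm=9500.0, sa=sa, bw=0.44, t=3.0)
    print(f"specific activity: {sa:.1f} cpm/pmol")
    print(f"unidirectional influx J_in = {j_in:.1f} pmol g^-1 h^-1")
    # a depleted fish showing the reported ~35% suppression
    print(f"depleted-fish example (65% of counts): "
          f"{physiology.zinc_influx(0.65 * 9500.0, sa, 0.44, 3.0):.1f} pmol g^-1 h^-1")

    # qPCR: fit a standard curve from a 10-fold dilution series, then quantify
    log10_copies = np.arange(2, 8)
    ct = -3.32 * log10_copies + 38.0
    slope, intercept, eff = physiology.fit_standard_curve(log10_copies, ct)
    print(f"standard curve: slope {slope:.2f}, intercept {intercept:.1f}, "
          f"efficiency {100 * eff:.0f}%")
    target = physiology.qpcr_copies(24.7, slope, intercept)
    reference = physiology.qpcr_copies(10.2, slope, intercept)
    norm = physiology.qpcr_relative_expression(24.7, slope, intercept, reference)
    print(f"target {target:.3g} copies / 18s {reference:.3g} copies "
          f"-> normalized expression {norm:.3g}")
    res = physiology.compare_groups([1.0, 0.9, 1.1, 1.2], [0.55, 0.6, 0.7, 0.62])
    print(f"group comparison (two-tailed unpaired t): t={res['t']:.2f}, "
          f"p={res['p']:.4f}, significant={res['significant']}")


if __name__ == "__main__":
    main()
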
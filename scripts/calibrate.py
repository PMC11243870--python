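"""Calibration of the under-specified architecture knobs.

The architecture description fixes the stage widths (32/64/128), the
three level-1 residual modules and the published complexity budgets of
the six variants, but leaves open the deeper repeat counts, the decoder
widths and the fusion internals.  This script searches that knob space
with a closed-form cost model and reports the configuration whose six
parameter counts reproduce the published table to the printed precision
(+-0.0005 M) while minimizing the multiply-accumulate error; the winning
values are frozen as the defaults of ``NetworkConfig``.

Run:  python scripts/calibrate.py [--verify-only]
"""

from __future__ import annotations

import argparse
import itertools
import sys

# published budgets: model id -> (params in M, MACs in G at 1024x512)
PUBLISHED = {
    1: (0.270, 6.754),
    2: (0.273, 6.679),
    3: (0.271, 6.716),
    4: (0.289, 7.260),
    5: (0.329, 7.158),
    6: (0.459, 8.430),
}

PX1, PX2, PX3 = 256 * 512, 128 * 256, 64 * 128  # pixels at H/2, H/4, H/8


def ca_cost(c: int, r: int) -> tuple[int, int]:
    """Channel attention (biased two-layer perceptron): (params, MACs)."""
    h = max(1, c // r)
    return 2 * c * h + h + c, 4 * c * h


SA_COST = (98, 0)  # spatial attention: bias-free 7x7 conv on 2 maps; MACs are px-dependent


def brm_cost(c2: int, px: int, mode: str, r: int = 16) -> tuple[int, int]:
    c = c2 // 2
    p, m = 12 * c * c + 4 * c, 12 * c * c * px
    for kind in {"HA": ("CA", "SA"), "SA": ("SA", "SA"), "CA": ("CA", "CA")}[mode]:
        if kind == "CA":
            cp, cm = ca_cost(c, r)
            p, m = p + cp, m + cm
        else:
            p, m = p + 98, m + 98 * px
    return p, m


def cbam_cost(c: int, px: int, r: int = 16) -> tuple[int, int]:
    h = max(1, c // r)
    return 2 * c * h + 98, 4 * c * h + 98 * px


def model_cost(mode: str, maf: bool, ppm: bool, n2: int, n3: int,
               f1: int, f2: int, ph: int, cw: int) -> tuple[int, int]:
    """(params, MACs) of one variant under the shared wiring rules."""
    p = m = 0

    def add(dp, dm):
        nonlocal p, m
        p, m = p + dp, m + dm

    add(9 * 3 * 29 + 64, 9 * 3 * 29 * PX1)          # stem 3->32
    add(9 * 32 * 32 + 128, 9 * 32 * 32 * PX2)       # down 32->64
    add(9 * 64 * 64 + 256, 9 * 64 * 64 * PX3)       # down 64->128
    for width, px, n in ((32, PX1, 3), (64, PX2, n2), (128, PX3, n3)):
        bp, bm = brm_cost(width, px, mode)
        add(n * bp, n * bm)
    full = maf and ppm
    if maf:
        for c, px in ((32, PX1), (64, PX2), (128, PX3)):
            add(*cbam_cost(c, px))
            if full:
                add(c * c + 2 * c, c * c * px)      # per-scale projection
        g = 1 if full else 2
        add(224 * 128 // g + 256, 224 * 128 // g * PX3)
    if ppm:
        # three branches reduce pre-pool at H/8; the 6x6 branch post-pool
        add(4 * (128 * 32 + 64), 3 * 128 * 32 * PX3 + 128 * 32 * 36)
        add(128 * 128 // 4 + 256, 128 * 128 // 4 * PX3)   # grouped 1x1 projection
        add(9 * 128 * 128 // 4 + 256, 9 * 128 * 128 // 4 * PX3)  # grouped 3x3 refinement
    if full:
        add(*brm_cost(128, PX3, mode))              # dilated refinement BRM
        add(9 * 128 * cw + 2 * cw + cw * 128 + 256,  # context block
            (9 * 128 * cw + cw * 128) * PX3)
    add((128 + 64) * f1 + 2 * f1, (128 + 64) * f1 * PX2)    # ffm1
    add((f1 + 32) * f2 + 2 * f2, (f1 + 32) * f2 * PX1)      # ffm2
    add(9 * f2 * ph + 2 * ph, 9 * f2 * ph * PX1)            # pre-head 3x3
    add(ph + 1, ph * PX1)                                   # 1x1 head
    return p, m


def variant_costs(n2, n3, f1, f2, ph, cw):
    out = {}
    for mid, (mode, maf, ppm) in {
        1: ("SA", 0, 0), 2: ("CA", 0, 0), 3: ("HA", 0, 0),
        4: ("HA", 1, 0), 5: ("HA", 0, 1), 6: ("HA", 1, 1),
    }.items():
        out[mid] = model_cost(mode, bool(maf), bool(ppm), n2, n3, f1, f2, ph, cw)
    return out


def params_exact(costs) -> bool:
    return all(round(costs[i][0] / 1e6, 3) == PUBLISHED[i][0] for i in PUBLISHED)


def mac_error(costs) -> float:
    # Model 4 is excluded from the MAC objective: its published 7.260 G is
    # arithmetically incompatible with its published +0.018 M parameter
    # delta (0.42 G of extra convolution work at the fusion scales needs
    # >= 3000 parameters, blowing the +-0.0005 M parameter window).
    return sum(abs(costs[i][1] / 1e9 - PUBLISHED[i][1]) for i in PUBLISHED if i != 4)


def search():
    best = None
    grid = itertools.product(
        range(2, 5), range(2, 5),            # n2, n3
        range(32, 81, 2), range(24, 65, 2),  # decoder widths f1, f2
        range(8, 41, 4), range(8, 33, 4),    # pre-head width, context width
    )
    for n2, n3, f1, f2, ph, cw in grid:
        if f2 > f1 or ph > f2:
            continue
        costs = variant_costs(n2, n3, f1, f2, ph, cw)
        if not params_exact(costs):
            continue
        err = mac_error(costs)
        if best is None or err < best[0]:
            best = (err, (n2, n3, f1, f2, ph, cw), costs)
    return best


def show(tag, costs):
    print(f"{tag}:")
    print("  model   params (M)  published   MACs (G)  published")
    for mid in sorted(costs):
        p, m = costs[mid]
        tp, tm = PUBLISHED[mid]
        print(f"  {mid}      {p/1e6:9.6f}  {tp:9.3f}  {m/1e9:9.3f}  {tm:9.3f}")


def verify_implementation():
    from elanet.complexity import count_macs, count_params
    from elanet.network import ELANet, make_ablation

    costs = {}
    for mid in PUBLISHED:
        net = ELANet(make_ablation(mid))
        costs[mid] = (count_params(net), count_macs(net, (512, 1024)))
    show("implementation (elanet.complexity)", costs)
    ok = params_exact(costs)
    print("parameter table reproduced to printed precision:", ok)
    return ok


def main(argv=None):
    args = argparse.ArgumentParser(description=__doc__)
    args.add_argument("--verify-only", action="store_true",
                      help="only check the frozen defaults against the table")
    opts = args.parse_args(argv)
    if not opts.verify_only:
        best = search()
        if best is None:
            print("no knob combination reproduces the parameter table")
            return 1
        err, (n2, n3, f1, f2, ph, cw), costs = best
        print(f"best knobs: n2={n2} n3={n3} decoder=({f1},{f2}) "
              f"head_width={ph} context_width={cw}  (sum |MAC err| {err:.3f} G)")
        show("cost model", costs)
    return 0 if verify_implementation() else 1


if __name__ == "__main__":
    sys.exit(main())
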
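"""Independent brute-force oracles shared by the stats test modules."""

import itertools

import numpy as np
import pandas as pd


def long_format(Y, factors):
    """subjects x cells tensor -> tidy long frame."""
    n = Y.shape[0]
    shape = Y.shape[1:]
    rows = []
    for s in range(n):
        for combo in itertools.product(*[range(k) for k in shape]):
            rows.append(
                {"subject": s, **{f: c for f, c in zip(factors, combo)}, "value": Y[(s,) + combo]}
            )
    return pd.DataFrame(rows)


def brute_force_two_way(Y):
    """Classical sums-of-squares enumeration for a subjects x a x b design."""
    n, a, b = Y.shape
    grand = Y.mean()
    mA = Y.mean(axis=(0, 2))
    mB = Y.mean(axis=(0, 1))
    mS = Y.mean(axis=(1, 2))
    mSA = Y.mean(axis=2)
    mSB = Y.mean(axis=1)
    mAB = Y.mean(axis=0)
    ss_a = n * b * ((mA - grand) ** 2).sum()
    ss_b = n * a * ((mB - grand) ** 2).sum()
    ss_sa = b * ((mSA - mA[None, :] - mS[:, None] + grand) ** 2).sum()
    ss_sb = a * ((mSB - mB[None, :] - mS[:, None] + grand) ** 2).sum()
    ss_ab = n * ((mAB - mA[:, None] - mB[None, :] + grand) ** 2).sum()
    resid = (
        Y
        - mSA[:, :, None]
        - mSB[:, None, :]
        - mAB[None, :, :]
        + mA[None, :, None]
        + mB[None, None, :]
        + mS[:, None, None]
        - grand
    )
    ss_sab = (resid**2).sum()
    F_a = (ss_a / (a - 1)) / (ss_sa / ((a - 1) * (n - 1)))
    F_b = (ss_b / (b - 1)) / (ss_sb / ((b - 1) * (n - 1)))
    F_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_sab / ((a - 1) * (b - 1) * (n - 1)))
    return F_a, F_b, F_ab
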
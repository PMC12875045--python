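"""Multi-contrast set logic deriving macrophage-EV protein signatures.

Three two-group contrasts over a shared protein universe define:

- pro-inflammatory component: DAPs more abundant in M1 vs M2;
- anti-inflammatory component: DAPs more abundant in M2 vs M1;
- TAM-enriched proteome: DAPs more abundant in TAM in either TAM-vs-M1 or
  TAM-vs-M2 (union of the up-in-TAM calls);
- unique TAM-EV signature: TAM-enriched minus (pro + anti);
- pro-/anti-inflammatory components of TAM-EVs: TAM-enriched intersected
  with pro / anti;
- exclusive M1 / M2 signatures: pro / anti minus TAM-enriched.

These eight sets obey exact partition identities (tam_unique, tam_pro and
tam_anti partition tam_enriched; |pro| = |m1_sig| + |tam_pro|; likewise for
anti), which downstream code and tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SignatureSets", "derive_signatures", "overlap_with_reference",
           "prognosis_split"]


@dataclass
class SignatureSets:
    pro: set
    anti: set
    tam_enriched: set
    tam_unique: set
    tam_pro: set
    tam_anti: set
    m1_sig: set
    m2_sig: set
    direction_conflicts: set  # up in TAM in one contrast, down in the other

    def counts(self) -> dict[str, int]:
        return {
            "pro": len(self.pro),
            "anti": len(self.anti),
            "tam_enriched": len(self.tam_enriched),
            "tam_unique": len(self.tam_unique),
            "tam_pro": len(self.tam_pro),
            "tam_anti": len(self.tam_anti),
            "m1_sig": len(self.m1_sig),
            "m2_sig": len(self.m2_sig),
        }


def _dap_sets(result: pd.DataFrame) -> tuple[set, set]:
    sig = result[result["dap"].astype(bool)]
    return (
        set(sig.index[sig["logFC"] > 0]),
        set(sig.index[sig["logFC"] < 0]),
    )


def derive_signatures(
    c_m1_m2: pd.DataFrame,
    c_tam_m1: pd.DataFrame,
    c_tam_m2: pd.DataFrame,
) -> SignatureSets:
    """Derive the signature sets from three contrast tables.

    Each table is a `differential` result with the first-named group as A
    (so logFC > 0 means up in M1 / TAM respectively). Proteins significant
    up-in-TAM in one TAM contrast but down-in-TAM in the other are excluded
    from tam_enriched and reported in ``direction_conflicts``.
    """
    universes = [set(c.index) for c in (c_m1_m2, c_tam_m1, c_tam_m2)]
    if universes[0] != universes[1] or universes[0] != universes[2]:
        raise ValueError("contrasts must share one protein universe")

    pro, anti = _dap_sets(c_m1_m2)
    up_tam_1, down_tam_1 = _dap_sets(c_tam_m1)
    up_tam_2, down_tam_2 = _dap_sets(c_tam_m2)

    conflicts = (up_tam_1 & down_tam_2) | (up_tam_2 & down_tam_1)
    tam_enriched = (up_tam_1 | up_tam_2) - conflicts

    tam_pro = tam_enriched & pro
    tam_anti = tam_enriched & anti
    tam_unique = tam_enriched - pro - anti
    return SignatureSets(
        pro=pro,
        anti=anti,
        tam_enriched=tam_enriched,
        tam_unique=tam_unique,
        tam_pro=tam_pro,
        tam_anti=tam_anti,
        m1_sig=pro - tam_enriched,
        m2_sig=anti - tam_enriched,
        direction_conflicts=conflicts,
    )


def overlap_with_reference(signature: set, reference: set) -> tuple[set, int]:
    """Intersection of a derived signature with an external candidate list."""
    common = set(signature) & set(reference)
    return common, len(common)


def _median_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Median with a distribution-free CI from binomial order statistics."""
    from scipy import stats

    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    med = float(np.median(x))
    if n < 2:
        return med, med, med
    lo_k = stats.binom.ppf((1 - level) / 2, n, 0.5)
    hi_k = stats.binom.isf((1 - level) / 2, n, 0.5)
    lo = x[int(max(lo_k, 0))]
    hi = x[int(min(hi_k, n - 1))]
    return med, float(lo), float(hi)


def prognosis_split(
    signature: set, hr_table: pd.DataFrame
) -> dict[str, dict]:
    """Partition a signature's significant proteins by prognostic direction.

    ``hr_table`` is indexed by protein with columns HR and significant.
    Proteins with HR > 1 associate with short relapse-free survival (bad
    prognosis), HR < 1 with long; only significant proteins are
    partitioned. Returns per-arm member lists plus the median HR with a
    95% order-statistic CI.
    """
    hrs = hr_table["HR"].astype(float)
    if (hrs <= 0).any():
        raise ValueError("hazard ratios must be positive")
    sig = hr_table[hr_table["significant"].astype(bool)]
    members = sig.loc[sig.index.intersection(list(signature))]
    short = members[members["HR"] > 1.0]
    long_ = members[members["HR"] < 1.0]
    out = {}
    for name, part in [("short_rfs", short), ("long_rfs", long_)]:
        if len(part):
            med, lo, hi = _median_ci(part["HR"].to_numpy())
        else:
            med = lo = hi = float("nan")
        out[name] = {
            "proteins": sorted(part.index),
            "n": len(part),
            "median_hr": med,
            "ci_low": lo,
            "ci_high": hi,
        }
    return out
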
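"""Enzyme ages from domain ages, and the era binning of the nd timeline.

An enzyme inherits its evolutionary age from the nd values of its
structural domains.  The default rule takes the *second oldest* domain:
a cooption of an old domain into a new enzyme is dated by the accepting
context rather than the ancient donor.  The alternative rule takes the
oldest domain outright.  Single-domain enzymes take their only domain's
age under either rule.

The [0, 1] timeline is cut into ten width-0.1 eras.  Bins are
right-closed, with era 1 additionally containing nd = 0, so nd = 0.1
falls into era 1 ("between nd = 0 and nd = 0.1") and nd = 1.0 into
era 10.
"""

from __future__ import annotations

from typing import Iterable, Literal, Mapping

import math

import pandas as pd

from metanet.io import Dataset

AgeRule = Literal["second_oldest", "oldest"]

N_ERAS = 10


def assign_enzyme_age(domain_ages: Iterable[float], rule: AgeRule = "second_oldest") -> float:
    """Age of an enzyme from the multiset of its domain nd values.

    ``oldest`` takes the minimum nd; ``second_oldest`` the second
    element of the ascending-sorted multiset (duplicates kept), falling
    back to the single value for single-domain enzymes.
    """
    ages = sorted(float(a) for a in domain_ages)
    if not ages:
        raise ValueError("enzyme has no domain ages (unpainted)")
    if rule == "oldest":
        return ages[0]
    if rule == "second_oldest":
        return ages[1] if len(ages) > 1 else ages[0]
    raise ValueError(f"unknown age rule: {rule!r}")


def assign_all_ages(ds: Dataset, rule: AgeRule = "second_oldest") -> dict[str, float]:
    """ec -> age for every painted enzyme in the dataset."""
    return {ec: assign_enzyme_age(ages, rule) for ec, ages in ds.domain_ages().items()}


def bin_to_era(nd: float, era_width: float = 0.1) -> int:
    """Era index (1-based) of an nd value; right-closed bins, era 1 holds 0."""
    if not 0.0 <= nd <= 1.0:
        raise ValueError(f"nd outside [0, 1]: {nd}")
    n_eras = round(1.0 / era_width)
    if nd == 0.0:
        return 1
    return min(n_eras, max(1, math.ceil(nd / era_width - 1e-12)))


def era_counts(ds: Dataset, ages: Mapping[str, float], era_width: float = 0.1) -> pd.DataFrame:
    """Mesonetwork × era table of first enzyme appearances.

    Each enzyme is counted once per mesonetwork it belongs to, in the
    single era of its assigned age; row sums therefore equal the number
    of distinct (aged) enzymes per mesonetwork.
    """
    n_eras = round(1.0 / era_width)
    meso_of = ds.meso_of()
    meso_codes = sorted(ds.hierarchy["meso_code"].unique())
    counts = pd.DataFrame(
        0,
        index=pd.Index(meso_codes, name="meso_code"),
        columns=pd.Index(range(1, n_eras + 1), name="era"),
    )
    pairs = {
        (meso_of[m], ec)
        for ec, m in zip(ds.membership["ec"], ds.membership["map_id"])
        if m in meso_of and ec in ages
    }
    for meso, ec in pairs:
        counts.loc[meso, bin_to_era(ages[ec], era_width)] += 1
    return counts


def color_bin(nd: float, n_bins: int) -> int:
    """Equal-width color bin of [0, 1]; bin 1 = most ancient (red end)."""
    if not 0.0 <= nd <= 1.0:
        raise ValueError(f"nd outside [0, 1]: {nd}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if nd == 0.0:
        return 1
    return min(n_bins, math.ceil(nd * n_bins - 1e-12))
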
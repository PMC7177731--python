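"""Poisson quantification of droplet digital PCR (ddPCR) assays.

In ddPCR a reaction is partitioned into ~17,000 droplets; template molecules
distribute over droplets approximately Poisson, so the fraction of *negative*
droplets estimates the Poisson zero class and the mean template occupancy is

    lambda = -ln(n_negative / n_total)    (copies per droplet).

Relative gene copy number is the ratio of target to reference occupancies,
scaled by the known copy count of the reference locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


def read_counts_csv(path) -> list["DropletAssay"]:
    """CSV with columns sample, target, n_total, n_negative (extra columns
    such as dilution are preserved on the assay as metadata-free hints)."""
    import pandas as pd
    df = pd.read_csv(path)
    required = {"target", "n_total", "n_negative"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts CSV missing columns: {sorted(missing)}")
    return [DropletAssay(n_total=int(r.n_total), n_negative=int(r.n_negative),
                         target=str(r.target)) for r in df.itertuples()]


class SaturationError(ValueError):
    """All droplets positive: concentration unresolvable, dilute the sample."""


@dataclass
class DropletAssay:
    """Positive/negative droplet counts for one amplicon."""

    n_total: int
    n_negative: int
    target: str = "target"
    droplet_volume_nl: float | None = None

    def __post_init__(self):
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0 <= self.n_negative <= self.n_total:
            raise ValueError("need 0 <= n_negative <= n_total")

    @property
    def n_positive(self) -> int:
        return self.n_total - self.n_negative

    @property
    def negative_fraction(self) -> float:
        return self.n_negative / self.n_total


def poisson_concentration(assay: DropletAssay, alpha: float = 0.05):
    """Mean template copies per droplet with a (1 - alpha) CI.

    The CI is a delta-method normal interval: the binomial standard error of
    the negative fraction f propagates through lambda = -ln f as
    se(lambda) = sqrt((1 - f) / (n f)).

    Returns ``(lam, (lo, hi))``. All-negative assays give lambda = 0 with a
    one-sided interval; all-positive assays raise :class:`SaturationError`.
    """
    if assay.n_negative == 0:
        raise SaturationError(
            f"{assay.target}: every droplet positive; dilute the sample")
    f = assay.negative_fraction
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    if assay.n_negative == assay.n_total:
        # zero concentration; upper bound from the rule-of-three-style
        # binomial bound on the positive fraction
        upper_pos = 1.0 - (alpha / 2.0) ** (1.0 / assay.n_total)
        return 0.0, (0.0, -math.log(1.0 - upper_pos))
    lam = -math.log(f)
    se = math.sqrt((1.0 - f) / (assay.n_total * f))
    return lam, (max(0.0, lam - z * se), lam + z * se)


def copies_per_microliter(assay: DropletAssay, alpha: float = 0.05):
    """Absolute concentration; requires droplet volume metadata."""
    if assay.droplet_volume_nl is None:
        raise ValueError("droplet volume metadata required for absolute "
                         "concentration")
    lam, (lo, hi) = poisson_concentration(assay, alpha)
    per_ul = 1000.0 / assay.droplet_volume_nl
    return lam * per_ul, (lo * per_ul, hi * per_ul)


def copy_number(target: DropletAssay, reference: DropletAssay,
                reference_copies: int = 1, alpha: float = 0.05):
    """Reference-normalised copy number with a delta-method CI.

    ratio = lambda_target / lambda_reference * reference_copies; the CI
    combines both relative errors on the log scale (the two assays are
    independent reactions).
    """
    lam_t, _ = poisson_concentration(target, alpha)
    lam_r, _ = poisson_concentration(reference, alpha)
    if lam_r == 0:
        raise ValueError("reference concentration is zero")
    ratio = lam_t / lam_r * reference_copies
    if lam_t == 0:
        return 0.0, (0.0, 0.0)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    rel = []
    for a, lam in ((target, lam_t), (reference, lam_r)):
        f = a.negative_fraction
        rel.append(math.sqrt((1.0 - f) / (a.n_total * f)) / lam)
    se_log = math.sqrt(rel[0] ** 2 + rel[1] ** 2)
    return ratio, (ratio * math.exp(-z * se_log), ratio * math.exp(z * se_log))
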
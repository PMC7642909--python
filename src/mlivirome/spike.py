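"""Absolute viral load estimation from an exogenous spike-in phage.

A phage of known genome size is added to a sample at a known titer
(pfu/ml) before virus-like-particle purification and sequencing. Under a
DNA-mass model — each particle contributes reads in proportion to its
genome length — the fraction f of reads mapping to the spike satisfies

    f / (1 - f) = titer * spike_genome_bp / (load * mean_genome_bp)

so the endogenous load (particles/ml) is

    load = titer * ((1 - f) / f) * (spike_genome_bp / mean_genome_bp)

with the mean endogenous phage genome conventionally assumed to be 40 kb.
A titration series (e.g. 1e5 / 1e6 / 1e7 pfu/ml) gives one estimate per
titer; the combined estimate is their mean +/- SD, and the linearity of f
against titer (OLS R^2) is the internal consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SpikeDesign",
    "ViralLoadEstimate",
    "spike_fraction",
    "estimate_viral_load",
    "fit_titration",
    "check_spike_absence",
]

DEFAULT_MEAN_GENOME_BP = 40_000


@dataclass(frozen=True)
class SpikeDesign:
    """A spike-in titration series for one sample.

    ``reads_total`` is the denominator of the spike fraction: total
    high-quality reads after host removal but *before* spike-read
    removal.
    """

    phage_id: str
    spike_genome_bp: float
    titers: tuple[float, ...]
    reads_total: tuple[int, ...]
    reads_spike: tuple[int, ...]
    mean_genome_bp: float = DEFAULT_MEAN_GENOME_BP

    def __post_init__(self) -> None:
        if not (len(self.titers) == len(self.reads_total) == len(self.reads_spike)):
            raise ValueError("titers, reads_total and reads_spike must align")
        if any(t <= 0 for t in self.titers):
            raise ValueError("titers must be > 0")
        if self.spike_genome_bp <= 0 or self.mean_genome_bp <= 0:
            raise ValueError("genome lengths must be > 0")
        if any(s > n for s, n in zip(self.reads_spike, self.reads_total)):
            raise ValueError("reads_spike cannot exceed reads_total")
        if any(s < 0 for s in self.reads_spike) or any(n <= 0 for n in self.reads_total):
            raise ValueError("read counts must be non-negative (totals > 0)")


@dataclass
class ViralLoadEstimate:
    """Per-titer and combined absolute viral load estimates."""

    per_titer: dict[float, float]
    mean: float
    sd: float
    r_squared: float  # NaN when fewer than 2 usable titers
    flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Viral load estimate (particles/ml)"]
        for t, est in self.per_titer.items():
            lines.append(f"  titer {t:.3g} pfu/ml -> {est:.4g}")
        lines.append(f"  combined: {self.mean:.4g} +/- {self.sd:.4g}")
        if np.isnan(self.r_squared):
            lines.append("  titration R^2: undefined (single titer)")
        else:
            lines.append(f"  titration R^2: {self.r_squared:.4f}")
        for fl in self.flags:
            lines.append(f"  flag: {fl}")
        return "\n".join(lines)


def spike_fraction(reads_spike: int, reads_total: int) -> float:
    """Fraction of reads aligning to the spike phage."""
    if reads_total <= 0:
        raise ValueError("reads_total must be > 0")
    if not 0 <= reads_spike <= reads_total:
        raise ValueError("reads_spike must be in [0, reads_total]")
    return reads_spike / reads_total


def estimate_viral_load(
    f: float,
    titer: float,
    spike_genome_bp: float,
    mean_genome_bp: float = DEFAULT_MEAN_GENOME_BP,
) -> float:
    """Endogenous viral load (particles/ml) from a spike read fraction.

    Exact inverse of the mass-model expectation: plugging the expected
    fraction for a known true load recovers that load identically.
    """
    if not 0.0 < f < 1.0:
        raise ValueError(
            "spike fraction must be strictly between 0 (spike undetected) "
            "and 1 (no endogenous signal)"
        )
    if titer <= 0 or spike_genome_bp <= 0 or mean_genome_bp <= 0:
        raise ValueError("titer and genome lengths must be > 0")
    return titer * ((1.0 - f) / f) * (spike_genome_bp / mean_genome_bp)


def fit_titration(design: SpikeDesign) -> ViralLoadEstimate:
    """Estimate viral load from a titration series.

    Per-titer loads are computed from each titer's spike fraction; the
    combined estimate is their mean and SD (ddof=1). R^2 comes from an
    ordinary least-squares fit of the spike fraction on the titer and is
    NaN (flagged) for a single titer.
    """
    flags: list[str] = []
    fracs = [spike_fraction(s, n) for s, n in zip(design.reads_spike, design.reads_total)]
    usable = [(t, f) for t, f in zip(design.titers, fracs) if 0.0 < f < 1.0]
    if not usable:
        raise ValueError("no titer has detectable spike reads (all spike fractions 0 or 1)")
    for t, f in zip(design.titers, fracs):
        if f == 0.0:
            flags.append(f"spike undetected at titer {t:.3g} pfu/ml; titer skipped")
        elif f == 1.0:
            flags.append(f"no endogenous reads at titer {t:.3g} pfu/ml; titer skipped")

    per_titer = {
        t: estimate_viral_load(f, t, design.spike_genome_bp, design.mean_genome_bp)
        for t, f in usable
    }
    estimates = np.array(list(per_titer.values()))
    mean = float(estimates.mean())
    sd = float(estimates.std(ddof=1)) if len(estimates) > 1 else 0.0

    if len(usable) >= 2:
        t_arr = np.array([t for t, _ in usable], dtype=float)
        f_arr = np.array([f for _, f in usable], dtype=float)
        res = stats.linregress(t_arr, f_arr)
        r_squared = float(res.rvalue**2)
    else:
        r_squared = float("nan")
        flags.append("single usable titer: titration R^2 undefined")
    return ViralLoadEstimate(per_titer=per_titer, mean=mean, sd=sd, r_squared=r_squared, flags=flags)


def check_spike_absence(
    reads_spike: int, reads_total: int, max_fraction: float = 1e-6
) -> str:
    """Classify background spike signal in an unspiked sample.

    Returns ``"absent"`` for zero spike reads, ``"trace"`` when the
    fraction is <= max_fraction (default one read per million), else
    ``"present"`` — a contamination or prior-exposure signal that makes
    the phage unsuitable as a spike for that subject.
    """
    f = spike_fraction(reads_spike, reads_total)
    if reads_spike == 0:
        return "absent"
    return "trace" if f <= max_fraction else "present"
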
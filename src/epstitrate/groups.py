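"""Functional-group classification of fitted pKa spectra.

Proton-binding sites of EPS fall into characteristic pKa windows:
carboxylic acids titrate around pKa 3-5.8, phosphoryl groups 6-8, amines
8-9 and hydroxyls 9-10. Binning a fitted discrete spectrum into these
classes and averaging over replicate titrations yields the per-class
ligand totals (mMol per gram EPS, reported mean +/- sd) that summarise a
sample's surface reactivity.

Boundary convention: each class is the half-open interval [lo, hi) except
the last, which is closed at its upper bound. This resolves the shared
boundaries (a site at pKa 8.0 is amine, not phosphoryl; 9.0 is hydroxyl)
deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chemistry import ConfigError, DataError
from .inversion import LigandSpectrum

__all__ = [
    "GroupClass",
    "FunctionalGroupScheme",
    "DEFAULT_SCHEME",
    "FunctionalGroupSummary",
    "UNASSIGNED",
    "bin_functional_groups",
    "aggregate_replicates",
    "render_table1_report",
]

#: Key under which sites falling in no class are totalled.
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class GroupClass:
    name: str
    pka_lo: float
    pka_hi: float

    def __post_init__(self) -> None:
        if not self.pka_lo < self.pka_hi:
            raise ConfigError(f"class {self.name!r}: lo must be < hi")


@dataclass(frozen=True)
class FunctionalGroupScheme:
    """Ordered, non-overlapping pKa classes."""

    classes: tuple[GroupClass, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        if not self.classes:
            raise ConfigError("scheme needs at least one class")
        for a, b in zip(self.classes, self.classes[1:]):
            # half-open [lo, hi): touching boundaries (hi == next lo) are fine
            if b.pka_lo < a.pka_hi:
                raise ConfigError(
                    f"classes {a.name!r} and {b.name!r} overlap under the "
                    "half-open convention"
                )

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.classes]

    def assign(self, pka: float) -> str | None:
        """Class name for a site pKa, or None if it falls in no class.

        Intervals are [lo, hi); an upper bound belongs to the class itself
        only when no following class starts there (the last class, or a
        class followed by a gap, is closed at its hi — so 5.8 is carboxyl
        while 8.0, shared between phosphoryl and amine, goes to amine).
        """
        for i, c in enumerate(self.classes):
            nxt = self.classes[i + 1] if i + 1 < len(self.classes) else None
            hi_closed = nxt is None or nxt.pka_lo > c.pka_hi
            if c.pka_lo <= pka < c.pka_hi or (hi_closed and pka == c.pka_hi):
                return c.name
        return None


#: Carboxyl / phosphoryl / amine / hydroxyl windows used throughout.
DEFAULT_SCHEME = FunctionalGroupScheme(
    classes=(
        GroupClass("Carboxyl", 3.0, 5.8),
        GroupClass("Phosphoryl", 6.0, 8.0),
        GroupClass("Amine", 8.0, 9.0),
        GroupClass("Hydroxyl", 9.0, 10.0),
    )
)


def bin_functional_groups(
    spectrum: LigandSpectrum, scheme: FunctionalGroupScheme = DEFAULT_SCHEME
) -> dict[str, float]:
    """Total ligand concentration per functional-group class.

    Every grid site is assigned to at most one class; mass at sites
    covered by no class is totalled under ``"unassigned"``. The returned
    dict always contains every class name plus ``"unassigned"``, in scheme
    order, and its values sum exactly to ``spectrum.total_LT``.
    """
    totals = {name: 0.0 for name in scheme.names}
    totals[UNASSIGNED] = 0.0
    for pka, lt in zip(spectrum.pka, spectrum.ligand_totals):
        cls = scheme.assign(float(pka))
        totals[cls if cls is not None else UNASSIGNED] += float(lt)
    return totals


@dataclass(frozen=True)
class FunctionalGroupSummary:
    """Replicate-aggregated per-class ligand totals for one sample.

    per_replicate maps class name -> list of replicate totals; mean and sd
    (sample standard deviation, n-1 denominator) are per class, with sd
    NaN when only one replicate is available. Units follow the inputs
    (mMol/g EPS in the reporting pipeline).
    """

    per_replicate: Mapping[str, tuple[float, ...]]
    mean: Mapping[str, float]
    sd: Mapping[str, float]
    n_replicates: int

    @property
    def class_names(self) -> list[str]:
        return list(self.mean.keys())


def aggregate_replicates(
    per_replicate_totals: Sequence[Mapping[str, float]]
) -> FunctionalGroupSummary:
    """Mean +/- sample sd of per-class totals over replicate fits.

    All replicates must share the same class set (same scheme). With a
    single replicate the sd is reported as NaN (not available).
    """
    if not per_replicate_totals:
        raise DataError("need at least one replicate")
    names = list(per_replicate_totals[0].keys())
    for t in per_replicate_totals[1:]:
        if list(t.keys()) != names:
            raise DataError("replicates were binned with inconsistent schemes")
    n = len(per_replicate_totals)
    per_rep = {name: tuple(t[name] for t in per_replicate_totals) for name in names}
    mean = {name: float(np.mean(per_rep[name])) for name in names}
    if n > 1:
        sd = {name: float(np.std(per_rep[name], ddof=1)) for name in names}
    else:
        sd = {name: float("nan") for name in names}
    return FunctionalGroupSummary(per_replicate=per_rep, mean=mean, sd=sd, n_replicates=n)


def _format_pm(mean: float, sd: float) -> str:
    if math.isnan(sd):
        return f"{mean:.3f} ± NA"
    return f"{mean:.3f} ± {sd:.3f}"


def render_table1_report(
    summaries: Mapping[str, FunctionalGroupSummary],
    scheme: FunctionalGroupScheme = DEFAULT_SCHEME,
    *,
    include_unassigned: bool = False,
) -> str:
    """Fixed-width summary table, one value column per sample.

    Columns: Functional Group | pKa Range | Average L_T (mMol/g EPS) per
    sample (in input order), values formatted ``mean ± sd`` to 3 decimals.
    Classes absent from a summary render as ``0.000 ± 0.000``.
    """
    if not summaries:
        raise DataError("need at least one summary to render")
    rows: list[list[str]] = []
    row_keys = [c.name for c in scheme.classes] + ([UNASSIGNED] if include_unassigned else [])
    for key in row_keys:
        if key == UNASSIGNED:
            label, rng = "Unassigned", "-"
        else:
            c = next(c for c in scheme.classes if c.name == key)
            label, rng = c.name, f"{c.pka_lo:g}–{c.pka_hi:g}"
        row = [label, rng]
        for summary in summaries.values():
            if key in summary.mean:
                row.append(_format_pm(summary.mean[key], summary.sd[key]))
            else:
                row.append("0.000 ± 0.000")
        rows.append(row)

    header = ["Functional Group", "pKa Range"] + list(summaries.keys())
    subheader = ["", ""] + ["Average L_T (mMol/g EPS)"] * len(summaries)
    widths = [
        max(len(r[i]) for r in [header, subheader, *rows]) for i in range(len(header))
    ]
    lines = []
    for r in [header, subheader]:
        lines.append("  ".join(v.ljust(w) for v, w in zip(r, widths)).rstrip())
    lines.append("  ".join("-" * w for w in widths))
    for r in rows:
        lines.append("  ".join(v.ljust(w) for v, w in zip(r, widths)).rstrip())
    return "\n".join(lines) + "\n"
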
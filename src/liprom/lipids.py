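"""Lipid species name parsing and fatty-acyl saturation categorization.

Names follow the shorthand used by targeted lipidomics panels::

    CLASS(C:D)                 single-chain species, e.g. LPC(18:2)
    CLASS(C:D/C:D[/C:D])       fully resolved chains, e.g. PC(16:0/20:4)
    CLASS(P-C:D/C:D)           plasmalogen/ether species, e.g. PE(P-18:1/20:4)
    TAG(C:D-FAc:d)             totals plus one identified chain

Each species is categorized into one of four saturation sub-classes:
odd total carbon count (ODD), saturated/mono-unsaturated (SFA_MUFA),
double-unsaturated (DUFA), poly-unsaturated (PUFA).  ODD takes precedence
over the double-bond rules; otherwise the deciding double-bond count is the
maximum over annotated chains when chains are known and the total double
bond count when they are not (single-chain classes and TAG totals).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .core import LIPID_CLASSES, QuantTable


class LipidNameError(ValueError):
    """Raised for names outside the supported grammar."""


class SaturationCategory(str, Enum):
    ODD = "ODD"
    SFA_MUFA = "SFA_MUFA"
    DUFA = "DUFA"
    PUFA = "PUFA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CATEGORIES: tuple[SaturationCategory, ...] = (
    SaturationCategory.ODD,
    SaturationCategory.SFA_MUFA,
    SaturationCategory.DUFA,
    SaturationCategory.PUFA,
)


@dataclass(frozen=True)
class LipidSpecies:
    """Parsed lipid species name."""

    raw_name: str
    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    chains: tuple[tuple[int, int], ...] = ()
    ether_flag: Optional[str] = None  # None | "P" | "O"
    known_fa: Optional[tuple[int, int]] = None  # TAG "total-FA" notation

    def __post_init__(self) -> None:
        if self.total_carbons <= 0:
            raise LipidNameError(f"{self.raw_name}: carbons must be positive")
        if self.total_double_bonds < 0:
            raise LipidNameError(f"{self.raw_name}: negative double bonds")
        if self.chains:
            c = sum(ch[0] for ch in self.chains)
            d = sum(ch[1] for ch in self.chains)
            if (c, d) != (self.total_carbons, self.total_double_bonds):
                raise LipidNameError(
                    f"{self.raw_name}: chain totals {c}:{d} inconsistent with "
                    f"{self.total_carbons}:{self.total_double_bonds}"
                )


_NAME_RE = re.compile(
    r"""^(?P<cls>[A-Za-z]+)\(
        (?:(?P<ether>[PO])-)?
        (?P<body>\d+:\d+(?:/\d+:\d+)*)
        (?:-FA(?P<fac>\d+):(?P<fad>\d+))?
        \)$""",
    re.VERBOSE,
)


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Raises :class:`LipidNameError` for names outside the grammar or with
    chain totals inconsistent with the leading C:D pair.
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise LipidNameError(f"unparseable lipid name: {name!r}")
    cls = m.group("cls").upper()
    if cls not in LIPID_CLASSES:
        raise LipidNameError(f"{name!r}: unknown lipid class {cls!r}")
    pairs = [tuple(int(x) for x in p.split(":")) for p in m.group("body").split("/")]
    known_fa = None
    if m.group("fac") is not None:
        if len(pairs) != 1:
            raise LipidNameError(f"{name!r}: -FA tag requires a single C:D total")
        known_fa = (int(m.group("fac")), int(m.group("fad")))
    ether = m.group("ether")
    if len(pairs) == 1:
        total_c, total_d = pairs[0]
        chains: tuple[tuple[int, int], ...] = ()
        if known_fa is None and cls != "TAG":
            # single-chain classes: the single C:D pair is the chain itself
            chains = (tuple(pairs[0]),)
    else:
        chains = tuple(tuple(p) for p in pairs)
        total_c = sum(p[0] for p in pairs)
        total_d = sum(p[1] for p in pairs)
    return LipidSpecies(
        raw_name=name.strip(),
        lipid_class=cls,
        total_carbons=total_c,
        total_double_bonds=total_d,
        chains=chains,
        ether_flag=ether,
        known_fa=known_fa,
    )


def categorize_saturation(species: LipidSpecies) -> SaturationCategory:
    """Assign the saturation sub-class of a parsed species.

    Odd total carbon count decides first, regardless of double bonds.  For
    even totals, the deciding double-bond count ``d`` is the maximum over
    annotated chains when chains are known; with only totals available
    (TAG shorthand) the species total double-bond count is used as a
    documented convention.
    """
    if species.total_carbons % 2 == 1:
        return SaturationCategory.ODD
    if species.chains:
        d = max(ch[1] for ch in species.chains)
    else:
        # totals-only notation (TAG shorthand): deciding count is the total
        d = species.total_double_bonds
    if d <= 1:
        return SaturationCategory.SFA_MUFA
    if d == 2:
        return SaturationCategory.DUFA
    return SaturationCategory.PUFA


def categorize_name(name: str) -> SaturationCategory:
    """Convenience: parse then categorize."""
    return categorize_saturation(parse_lipid_name(name))


def annotate_features(table: QuantTable) -> pd.DataFrame:
    """Annotation table for every lipid feature of a quant table.

    Returns a DataFrame indexed by feature id with columns ``lipid_class``,
    ``total_carbons``, ``total_double_bonds``, ``ether_flag`` and
    ``category``.
    """
    rows = {}
    for feat in table.lipid_features:
        sp = parse_lipid_name(feat)
        rows[feat] = {
            "lipid_class": sp.lipid_class,
            "total_carbons": sp.total_carbons,
            "total_double_bonds": sp.total_double_bonds,
            "ether_flag": sp.ether_flag or "",
            "category": categorize_saturation(sp).value,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("feature_id")


def class_totals(table: QuantTable) -> pd.DataFrame:
    """Per-sample lipid class totals (sum of member species concentrations).

    Missing cells contribute zero; classes with no member species are
    reported as all-zero columns only if present in the metadata.
    """
    lipids = table.lipid_features
    meta = table.feature_meta.loc[lipids]
    out = {}
    for cls, feats in meta.groupby("lipid_class").groups.items():
        out[str(cls)] = table.values[list(feats)].sum(axis=1, skipna=True)
    totals = pd.DataFrame(out, index=table.values.index)
    return totals.reindex(sorted(totals.columns), axis=1)


def subclass_abundance(table: QuantTable) -> pd.DataFrame:
    """%Abundance of each (lipid class, saturation category) per sample.

    For each sample and class, the four category percentages sum to 100.
    Classes whose total is zero for a sample yield ``NaN`` percentages for
    that sample (flagged rather than fabricated).
    """
    ann = annotate_features(table)
    lipids = list(ann.index)
    vals = table.values[lipids]
    pieces = {}
    for (cls, cat), feats in ann.groupby(["lipid_class", "category"]).groups.items():
        pieces[(str(cls), str(cat))] = vals[list(feats)].sum(axis=1, skipna=True)
    classes = sorted({c for c, _ in pieces})
    cols = {}
    for cls in classes:
        total = sum(
            pieces.get((cls, cat.value), pd.Series(0.0, index=vals.index))
            for cat in CATEGORIES
        )
        denom = total.where(total > 0)
        for cat in CATEGORIES:
            num = pieces.get((cls, cat.value), pd.Series(0.0, index=vals.index))
            cols[(cls, cat.value)] = 100.0 * num / denom
    out = pd.DataFrame(cols, index=vals.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["lipid_class", "category"])
    return out


def abundance_group_summary(abund: pd.DataFrame, design) -> pd.DataFrame:
    """Group mean %Abundance with 95% t-CIs, relative to the reference group.

    Returns a tidy frame with one row per (group, lipid_class, category) and
    columns ``mean``, ``ci_low``, ``ci_high``, ``diff_vs_reference`` and
    ``n``.  Singleton groups yield NaN CIs.
    """
    from scipy import stats

    ref_means = abund.loc[design.samples_in(design.reference)].mean(axis=0)
    rows = []
    for group in design.groups:
        sub = abund.loc[design.samples_in(group)]
        n = len(sub)
        means = sub.mean(axis=0)
        sds = sub.std(axis=0, ddof=1)
        if n >= 2:
            half = stats.t.ppf(0.975, n - 1) * sds / float(n) ** 0.5
        else:
            half = pd.Series(float("nan"), index=means.index)
        for (cls, cat) in abund.columns:
            rows.append(
                {
                    "group": group,
                    "lipid_class": cls,
                    "category": cat,
                    "n": n,
                    "mean": means[(cls, cat)],
                    "ci_low": means[(cls, cat)] - half[(cls, cat)],
                    "ci_high": means[(cls, cat)] + half[(cls, cat)],
                    "diff_vs_reference": means[(cls, cat)] - ref_means[(cls, cat)],
                }
            )
    return pd.DataFrame(rows)
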
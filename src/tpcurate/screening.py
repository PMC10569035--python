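"""Suspect-list screening stage: TP labeling, parent linkage, XlogP shift.

Given a table of tentatively identified compounds (from a non-target
screening workflow, already resolved to InChIKeys) and a TP suspect list
exported from a transformations library, this module labels which
identified compounds are known transformation products, links each
labeled TP to its identified parent compounds, and tests the directional
hypothesis that TPs are more polar than their parents — a one-sided
paired Wilcoxon signed-rank test on XlogP, the computed octanol-water
partition coefficient (lower = more water-mobile).

Matching is identifier-based (InChIKey, exact or stereo-agnostic
skeleton), never mass-based: mass-spectral identification happens
upstream, outside this package.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .chem import INCHIKEY_RE
from .errors import SchemaError, ScreeningError
from .library import SuspectEntry

logger = logging.getLogger(__name__)

LABEL_LEVELS = ("exact", "skeleton")


@dataclass(frozen=True)
class IdentifiedCompound:
    """One tentatively identified compound from a screening result table."""

    name: str
    inchikey: str
    cid: int | None = None
    xlogp: float | None = None

    def __post_init__(self):
        if not INCHIKEY_RE.match(self.inchikey):
            raise ValueError(f"malformed InChIKey {self.inchikey!r} for {self.name!r}")

    @property
    def skeleton(self) -> str:
        return self.inchikey[:14]


@dataclass(frozen=True)
class LabeledCompound:
    """An identified compound with its TP label and matched suspects."""

    compound: IdentifiedCompound
    is_tp: bool
    matched_suspects: tuple[SuspectEntry, ...] = ()


@dataclass(frozen=True)
class ParentTPPair:
    """An identified parent and identified TP linked through the library.

    ``via`` lists the linking predecessor InChIKeys from the suspect
    entry the TP matched (never empty).
    """

    parent: IdentifiedCompound
    tp: IdentifiedCompound
    via: tuple[str, ...]


def label_tps(
    compounds: list[IdentifiedCompound],
    suspects: list[SuspectEntry],
    level: str = "exact",
) -> list[LabeledCompound]:
    """Label each identified compound as TP / not-TP against a suspect list.

    A compound is a TP iff its InChIKey matches a suspect entry at the
    chosen level (``exact``: full key; ``skeleton``: first 14 characters,
    so stereoisomers of a listed TP also match). Non-matching compounds
    are kept with ``is_tp=False`` — the output always has the same length
    as the input.
    """
    if level not in LABEL_LEVELS:
        raise ValueError(f"unknown label level {level!r}; expected one of {LABEL_LEVELS}")
    key = (lambda ik: ik) if level == "exact" else (lambda ik: ik[:14])
    by_key: dict[str, list[SuspectEntry]] = {}
    for s in suspects:
        by_key.setdefault(key(s.inchikey), []).append(s)
    out = []
    for c in compounds:
        matches = tuple(by_key.get(key(c.inchikey), ()))
        out.append(LabeledCompound(compound=c, is_tp=bool(matches), matched_suspects=matches))
    return out


def link_parent_pairs(
    labeled: list[LabeledCompound], level: str = "exact"
) -> tuple[list[ParentTPPair], list[IdentifiedCompound]]:
    """Link each labeled TP to identified parent compounds.

    A parent is any compound in the same identified list (TP-labeled or
    not) whose InChIKey matches, at the chosen level, a predecessor key of
    a suspect entry the TP matched. A TP with k identified parents yields
    k pairs; a TP with none goes to the orphan list — orphans are real
    observations (parent degraded below detection, misidentification, or
    direct release of the TP itself). Self-pairs (parent == TP structure)
    are excluded and logged.
    """
    if level not in LABEL_LEVELS:
        raise ValueError(f"unknown label level {level!r}; expected one of {LABEL_LEVELS}")
    key = (lambda ik: ik) if level == "exact" else (lambda ik: ik[:14])
    identified_by_key: dict[str, list[IdentifiedCompound]] = {}
    for lc in labeled:
        identified_by_key.setdefault(key(lc.compound.inchikey), []).append(lc.compound)

    pairs: list[ParentTPPair] = []
    orphans: list[IdentifiedCompound] = []
    for lc in labeled:
        if not lc.is_tp:
            continue
        tp = lc.compound
        found_parent = False
        seen_parents: set[str] = set()
        for suspect in lc.matched_suspects:
            for pred_ik in suspect.predecessor_inchikeys:
                for parent in identified_by_key.get(key(pred_ik), ()):
                    if key(parent.inchikey) == key(tp.inchikey):
                        logger.info(
                            "excluding self-pair for %s (%s)", tp.name, tp.inchikey
                        )
                        continue
                    if parent.inchikey in seen_parents:
                        continue
                    seen_parents.add(parent.inchikey)
                    pairs.append(ParentTPPair(parent=parent, tp=tp, via=(pred_ik,)))
                    found_parent = True
        if not found_parent:
            orphans.append(tp)
    return pairs, orphans


@dataclass
class XlogpComparison:
    """Paired XlogP comparison between parents and their TPs.

    ``p_one_sided`` tests the alternative that TP XlogP is lower than the
    parent's (Wilcoxon signed-rank, zero differences dropped; exact null
    distribution for n_used <= 25, normal approximation with continuity
    correction above). Kernel-density curves (Gaussian kernel, Silverman
    bandwidth) are provided for plotting the two distributions.
    """

    n_pairs: int
    n_used: int
    n_excluded_missing: int
    n_zero_differences: int
    median_parent_xlogp: float
    median_tp_xlogp: float
    statistic: float
    p_one_sided: float
    p_two_sided: float
    method: str
    density_grid: list[float] = field(default_factory=list)
    parent_density: list[float] = field(default_factory=list)
    tp_density: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_used": self.n_used,
            "n_excluded_missing": self.n_excluded_missing,
            "n_zero_differences": self.n_zero_differences,
            "median_parent_xlogp": self.median_parent_xlogp,
            "median_tp_xlogp": self.median_tp_xlogp,
            "statistic": self.statistic,
            "p_one_sided": self.p_one_sided,
            "p_two_sided": self.p_two_sided,
            "method": self.method,
            "density_grid": self.density_grid,
            "parent_density": self.parent_density,
            "tp_density": self.tp_density,
        }


EXACT_N_MAX = 25  # exact signed-rank null up to here, normal approx beyond


def xlogp_compare(pairs: list[ParentTPPair], density_points: int = 128) -> XlogpComparison:
    """Compare XlogP of TPs against their parents over linked pairs.

    Pairs missing either XlogP value are excluded and counted. Raises
    :class:`ScreeningError` when no usable pair remains (including the
    degenerate all-zero-differences case) rather than returning NaNs.
    """
    parent_vals, tp_vals = [], []
    n_missing = 0
    for p in pairs:
        if p.parent.xlogp is None or p.tp.xlogp is None:
            n_missing += 1
            continue
        parent_vals.append(float(p.parent.xlogp))
        tp_vals.append(float(p.tp.xlogp))
    if not parent_vals:
        raise ScreeningError("no pair has XlogP values on both sides")
    parent_arr = np.asarray(parent_vals)
    tp_arr = np.asarray(tp_vals)
    diffs = tp_arr - parent_arr
    n_zero = int(np.sum(diffs == 0))
    n_used = int(np.sum(diffs != 0))
    if n_used == 0:
        raise ScreeningError("all paired XlogP differences are zero; nothing to test")

    method = "exact" if n_used <= EXACT_N_MAX else "approx"
    kwargs = dict(zero_method="wilcox", method=method)
    if method == "approx":
        kwargs["correction"] = True
    res_less = stats.wilcoxon(tp_arr, parent_arr, alternative="less", **kwargs)
    res_two = stats.wilcoxon(tp_arr, parent_arr, alternative="two-sided", **kwargs)

    grid, pdens, tdens = [], [], []
    if len(parent_arr) >= 2 and density_points > 0:
        lo = float(min(parent_arr.min(), tp_arr.min())) - 2.0
        hi = float(max(parent_arr.max(), tp_arr.max())) + 2.0
        grid_arr = np.linspace(lo, hi, density_points)
        try:
            pk = stats.gaussian_kde(parent_arr, bw_method="silverman")
            tk = stats.gaussian_kde(tp_arr, bw_method="silverman")
            grid = grid_arr.tolist()
            pdens = pk(grid_arr).tolist()
            tdens = tk(grid_arr).tolist()
        except np.linalg.LinAlgError:  # degenerate (constant) sample
            pass

    return XlogpComparison(
        n_pairs=len(pairs),
        n_used=n_used,
        n_excluded_missing=n_missing,
        n_zero_differences=n_zero,
        median_parent_xlogp=float(np.median(parent_arr)),
        median_tp_xlogp=float(np.median(tp_arr)),
        statistic=float(res_less.statistic),
        p_one_sided=float(res_less.pvalue),
        p_two_sided=float(res_two.pvalue),
        method=method,
        density_grid=grid,
        parent_density=pdens,
        tp_density=tdens,
    )


def plot_xlogp_densities(comparison: XlogpComparison, path: str | Path) -> None:
    """Write a density plot of parent vs TP XlogP distributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(comparison.density_grid, comparison.parent_density, label="parents")
    ax.plot(comparison.density_grid, comparison.tp_density, label="TPs")
    ax.set_xlabel("XlogP")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

IDENTIFIED_COLUMNS = ["name", "cid", "inchikey", "xlogp"]
LABEL_COLUMNS = ["name", "cid", "inchikey", "xlogp", "is_tp", "matched_suspect_inchikeys"]
PAIR_COLUMNS = [
    "parent_name",
    "parent_inchikey",
    "parent_xlogp",
    "tp_name",
    "tp_inchikey",
    "tp_xlogp",
    "via_predecessor_inchikeys",
]


def _check_header(header, expected, path):
    if header != expected:
        missing = [c for c in expected if c not in (header or [])]
        unknown = [c for c in (header or []) if c not in expected]
        raise SchemaError(
            f"{path}: missing={missing} unknown={unknown}", missing=missing, unknown=unknown
        )


def read_identified_csv(path: str | Path) -> list[IdentifiedCompound]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        _check_header(next(reader, None), IDENTIFIED_COLUMNS, str(path))
        out = []
        for name, cid, ik, xlogp in reader:
            out.append(
                IdentifiedCompound(
                    name=name,
                    cid=int(cid) if cid else None,
                    inchikey=ik,
                    xlogp=float(xlogp) if xlogp else None,
                )
            )
    return out


def write_identified_csv(compounds: list[IdentifiedCompound], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(IDENTIFIED_COLUMNS)
        for c in compounds:
            w.writerow(
                [
                    c.name,
                    "" if c.cid is None else c.cid,
                    c.inchikey,
                    "" if c.xlogp is None else f"{c.xlogp:.3f}",
                ]
            )


def write_labels_csv(labeled: list[LabeledCompound], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(LABEL_COLUMNS)
        for lc in labeled:
            c = lc.compound
            w.writerow(
                [
                    c.name,
                    "" if c.cid is None else c.cid,
                    c.inchikey,
                    "" if c.xlogp is None else f"{c.xlogp:.3f}",
                    "true" if lc.is_tp else "false",
                    ";".join(s.inchikey for s in lc.matched_suspects),
                ]
            )


def write_pairs_csv(pairs: list[ParentTPPair], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PAIR_COLUMNS)
        for p in pairs:
            w.writerow(
                [
                    p.parent.name,
                    p.parent.inchikey,
                    "" if p.parent.xlogp is None else f"{p.parent.xlogp:.3f}",
                    p.tp.name,
                    p.tp.inchikey,
                    "" if p.tp.xlogp is None else f"{p.tp.xlogp:.3f}",
                    ";".join(p.via),
                ]
            )


def write_orphans_csv(orphans: list[IdentifiedCompound], path: str | Path) -> None:
    write_identified_csv(orphans, path)


def write_comparison_json(comparison: XlogpComparison, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(comparison.to_dict(), fh, indent=2)
        fh.write("\n")
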
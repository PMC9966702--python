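"""Sliding-window physicochemical profiles and interface contrasts.

Predicted interface peptides tend to differ systematically from the rest
of the sequence — e.g. in charge, polarity, hydrophilicity, or helix
propensity.  This module computes windowed-mean property profiles along a
protein from standard amino-acid scales and tests whether a property
differs between predicted hot-spot columns and the remainder using a
rank statistic with a seeded permutation p-value.

Eight canonical literature scales ship as package data (TSV, trivially
user-replaceable): Kyte–Doolittle hydrophobicity, Hopp–Woods
hydrophilicity, Grantham polarity, integer side-chain charge at pH 7,
Charton polarizability, Zamyatnin residue volume, Chou–Fasman helix
propensity, and Tien et al. theoretical maximum SASA.  The "secondary
structure similarity" profile reported alongside the others is the
helix-propensity profile (interfaces here are helix-dominated); it is a
proxy, not a structure-derived score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .alignment import GAP
from .core import HotspotRectangle

BUILTIN_SCALES = (
    "hydrophobicity",
    "hydrophilicity",
    "polarity",
    "charge",
    "polarizability",
    "volume",
    "helix_propensity",
    "sasa",
)

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class PropertyScale:
    """One value per amino acid; gaps contribute nothing to averages."""

    name: str
    values: dict[str, float]
    citation: str = ""

    def __post_init__(self) -> None:
        missing = _AA20 - set(self.values)
        extra = set(self.values) - _AA20
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r} must define exactly the 20 amino acids "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]


def load_scale(name_or_path: str | Path) -> PropertyScale:
    """Load a builtin scale by name, or any (residue, value) TSV by path."""
    name = str(name_or_path)
    if name in BUILTIN_SCALES:
        text = files("spdca.data.scales").joinpath(f"{name}.tsv").read_text()
        citation = text.splitlines()[0].lstrip("# ").strip()
        import io

        df = pd.read_csv(io.StringIO(text), sep="\t", comment="#")
    else:
        path = Path(name_or_path)
        citation = ""
        df = pd.read_csv(path, sep="\t", comment="#")
        name = path.stem
    return PropertyScale(
        name=name,
        values={str(r): float(v) for r, v in zip(df["residue"], df["value"])},
        citation=citation,
    )


@dataclass
class PropertyProfile:
    """Windowed-mean property values, one per sequence position.

    Positions whose window contains only gaps are NaN.
    """

    protein: str
    scale: str
    window: int
    values: np.ndarray


def property_profile(
    seq: str | np.ndarray,
    scale: PropertyScale,
    window: int = 9,
    protein: str = "",
) -> PropertyProfile:
    """Mean scale value over a centered window of ``window`` residues.

    The window is clipped at the sequence ends and gap positions are
    excluded from the average, so the profile is defined on alignment
    coordinates as well as on plain sequences.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    chars = np.array(list(seq), dtype="U1") if isinstance(seq, str) else np.asarray(seq, dtype="U1")
    n = chars.size
    vals = np.array([scale.values.get(c, np.nan) for c in chars])
    ok = ~np.isnan(vals)   # gaps / unknown symbols drop out of the mean
    half = window // 2
    # cumulative sums give O(n) windowed means
    cs = np.concatenate([[0.0], np.cumsum(np.where(ok, vals, 0.0))])
    cn = np.concatenate([[0], np.cumsum(ok.astype(int))])
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        cnt = cn[hi] - cn[lo]
        out[i] = (cs[hi] - cs[lo]) / cnt if cnt else np.nan
    return PropertyProfile(protein=protein, scale=scale.name, window=window, values=out)


def write_profile_tsv(profile: PropertyProfile, seq: str, path: str | Path) -> None:
    pd.DataFrame(
        {
            "position": np.arange(1, profile.values.size + 1),
            "residue": list(seq),
            "value": profile.values,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class ContrastSummary:
    """Inside-vs-outside comparison of a profile over hot-spot columns."""

    scale: str
    axis: str
    mean_inside: float
    mean_outside: float
    difference: float
    statistic: float          # rank-sum of inside positions (tie-corrected ranks)
    p_value: float            # seeded two-sided permutation p-value
    n_inside: int
    n_outside: int
    n_permutations: int


def _hotspot_columns(
    rects: list[HotspotRectangle], axis: str, length: int
) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for r in rects:
        start, end = (r.start_a, r.end_a) if axis == "A" else (r.start_b, r.end_b)
        if start < 1 or end > length:
            raise ValueError(
                f"rectangle [{start}, {end}] outside sequence of length {length}"
            )
        mask[start - 1 : end] = True
    return mask


def interface_contrast(
    profile: PropertyProfile,
    rects: list[HotspotRectangle],
    axis: str = "A",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> ContrastSummary:
    """Does the property differ at predicted interfaces vs the rest?

    Inside columns are the union of the rectangles' spans on the chosen
    axis (no double counting).  The statistic is the rank-sum of inside
    positions; its null distribution is estimated by permuting column
    labels ``n_permutations`` times with a seeded generator, and the
    two-sided p-value uses the add-one rule.
    """
    if axis not in ("A", "B"):
        raise ValueError("axis must be 'A' or 'B'")
    if not rects:
        raise ValueError("empty hot-spot set: nothing to contrast")
    vals = profile.values
    defined = ~np.isnan(vals)
    inside = _hotspot_columns(rects, axis, vals.size)
    v = vals[defined]
    ins = inside[defined]
    k, n = int(ins.sum()), v.size
    if k == 0 or k == n:
        raise ValueError("hot-spot columns cover none or all defined positions")

    # snap values equal to within 1e-9 relative before ranking, so that
    # floating-point jitter from the windowed means cannot break ties
    vscale = float(np.max(np.abs(v))) or 1.0
    ranks = scipy.stats.rankdata(np.round(v / (vscale * 1e-9)))
    observed = float(ranks[ins].sum())
    expected = k * (n + 1) / 2.0

    rng = np.random.default_rng(seed)
    # vectorized label permutations: argsort of uniforms gives random subsets
    u = rng.random((n_permutations, n))
    idx = np.argpartition(u, k - 1, axis=1)[:, :k]
    null = ranks[idx].sum(axis=1)
    extreme = np.abs(null - expected) >= abs(observed - expected) - 1e-12
    p = (1.0 + int(extreme.sum())) / (n_permutations + 1.0)

    return ContrastSummary(
        scale=profile.scale,
        axis=axis,
        mean_inside=float(v[ins].mean()),
        mean_outside=float(v[~ins].mean()),
        difference=float(v[ins].mean() - v[~ins].mean()),
        statistic=observed,
        p_value=float(p),
        n_inside=k,
        n_outside=n - k,
        n_permutations=n_permutations,
    )


def contrast_table(
    seq: str,
    rects: list[HotspotRectangle],
    axis: str = "A",
    scales: tuple[str, ...] = BUILTIN_SCALES,
    window: int = 9,
    seed: int = 0,
    protein: str = "",
) -> pd.DataFrame:
    """Contrast every scale at once; one row per property."""
    rows = []
    for name in scales:
        scale = load_scale(name)
        prof = property_profile(seq, scale, window=window, protein=protein)
        c = interface_contrast(prof, rects, axis=axis, seed=seed)
        rows.append(
            {
                "scale": name,
                "mean_inside": c.mean_inside,
                "mean_outside": c.mean_outside,
                "difference": c.difference,
                "p_value": c.p_value,
            }
        )
    return pd.DataFrame(rows)
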
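"""Cross-channel spot pairing and single/double/triple classification.

A nascent spot marks an actively transcribing locus.  When two or three
probed genes burst in the same cell their spots sit within a nuclear-scale
distance of one another; operationally, spots from distinct channels whose
centres lie within a co-localization radius (default 500 nm) are grouped
into one record.  Records with one, two or three members are *singles*,
*doubles* and *triples*.

Grouping is greedy globally-closest-first: the smallest unassigned
cross-channel distance within the radius founds (or extends) a record, and
a third-channel spot joins an existing record only if it is within the
radius of every current member (clique rule).  Each spot belongs to exactly
one record, so per-channel totals are conserved by construction — asserted
on every run.

`expected_random_coloc` gives the co-occurrence expected if all genes burst
independently: model (a) counts cells active for both genes by chance alone
(E = n_A n_B / C); model (b) multiplies by the geometric probability that
two (or three) points placed uniformly in a nuclear sphere fall within the
co-localization radius, estimated by Monte Carlo, and also reports a
predictive interval for the observed count under that null.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "ColocParams",
    "ColocRecord",
    "pair_candidates",
    "classify_cooccurrence",
    "coloc_fraction",
    "expected_random_coloc",
]


@dataclass
class ColocParams:
    """Geometry of the co-localization search.

    ``search_halfwidth`` is half the side of the square search window around
    each spot (default 1950 nm, i.e. a 3.9 x 3.9 um square); ``coloc_radius``
    is the centre-to-centre distance that defines co-localization (500 nm).
    ``frame`` selects 2D-projected or full 3D distances — counting uses the
    projected frame (tissue sections are classified on 2D-fit centres),
    while nanoscale distance analysis uses 3D.
    """

    search_halfwidth: float = 1950.0  # nm
    coloc_radius: float = 500.0  # nm
    nuclear_radius: float = 3000.0  # nm
    frame: str = "2d"  # "2d" or "3d"
    triple_rule: str = "clique"  # "clique" or "chain"

    def __post_init__(self) -> None:
        if self.coloc_radius >= 2 * self.search_halfwidth:
            raise ValueError("coloc_radius must be smaller than the search square side")
        if min(self.search_halfwidth, self.coloc_radius, self.nuclear_radius) <= 0:
            raise ValueError("all geometric parameters must be positive")
        if self.frame not in ("2d", "3d"):
            raise ValueError("frame must be '2d' or '3d'")
        if self.triple_rule not in ("clique", "chain"):
            raise ValueError("triple_rule must be 'clique' or 'chain'")


@dataclass
class ColocRecord:
    """A maximal group of mutually proximal spots from distinct channels."""

    members: list[tuple[str, int]]  # (channel, row index into that channel's table)
    distances: dict[tuple[str, str], float]

    @property
    def label(self) -> str:
        if len(self.members) == 1:
            return "single"
        chans = ",".join(sorted(ch for ch, _ in self.members))
        return f"double:{chans}" if len(self.members) == 2 else "triple"

    @property
    def channels(self) -> set[str]:
        return {ch for ch, _ in self.members}


def _coords(table: pd.DataFrame, frame: str) -> np.ndarray:
    cols = ["x_nm", "y_nm"] if frame == "2d" else ["x_nm", "y_nm", "z_nm"]
    return table[cols].to_numpy(dtype=float)


def _accepted(table: pd.DataFrame) -> pd.DataFrame:
    if "accepted" in table.columns:
        return table[table["accepted"].astype(bool)].reset_index(drop=True)
    return table.reset_index(drop=True)


def _check_registered(tables: Mapping[str, pd.DataFrame],
                      transforms: Mapping | None) -> None:
    if not transforms:
        return
    for ch in tables:
        t = transforms.get(ch)
        if t is not None and not getattr(t, "is_identity", True):
            raise ValueError(
                f"channel {ch} has a non-identity chromatic transform; apply "
                "registration before co-localization analysis"
            )


def pair_candidates(spots_a: pd.DataFrame, spots_b: pd.DataFrame,
                    params: ColocParams | None = None,
                    channel_a: str = "A", channel_b: str = "B") -> pd.DataFrame:
    """All cross-channel pairs whose in-plane offsets fit the search square.

    Mirrors the validation procedure of searching a square window around
    every spot of one probe for spots of the other and recording the
    centre-to-centre distance.  Symmetric: pair (a, b) equals pair (b, a).
    """
    if params is None:
        params = ColocParams()
    a = _accepted(spots_a)
    b = _accepted(spots_b)
    rows: list[dict] = []
    if len(a) and len(b):
        ax = a["x_nm"].to_numpy(float)
        ay = a["y_nm"].to_numpy(float)
        bx = b["x_nm"].to_numpy(float)
        by = b["y_nm"].to_numpy(float)
        # Chebyshev KD-tree query = square window
        tree = cKDTree(np.column_stack([bx, by]))
        hits = tree.query_ball_point(np.column_stack([ax, ay]),
                                     r=params.search_halfwidth, p=np.inf)
        coords_a = _coords(a, params.frame)
        coords_b = _coords(b, params.frame)
        for i, js in enumerate(hits):
            for j in js:
                d = float(np.linalg.norm(coords_a[i] - coords_b[j]))
                rows.append(dict(channel_a=channel_a, idx_a=int(a.index[i]),
                                 channel_b=channel_b, idx_b=int(b.index[j]),
                                 distance_nm=d,
                                 dx_nm=float(ax[i] - bx[j]), dy_nm=float(ay[i] - by[j])))
    return pd.DataFrame(rows, columns=["channel_a", "idx_a", "channel_b", "idx_b",
                                       "distance_nm", "dx_nm", "dy_nm"])


def classify_cooccurrence(tables: Mapping[str, pd.DataFrame],
                          params: ColocParams | None = None,
                          transforms: Mapping | None = None
                          ) -> tuple[list[ColocRecord], pd.DataFrame]:
    """Group spots into disjoint single/double/triple records.

    Returns the records plus a per-channel summary table with columns
    ``total``, ``single``, one ``double:<pair>`` column per channel pair and
    ``triple``.  Per-channel totals are conserved (asserted).
    """
    if params is None:
        params = ColocParams()
    _check_registered(tables, transforms)
    acc = {ch: _accepted(t) for ch, t in tables.items()}
    channels = sorted(acc)
    coords = {ch: _coords(t, params.frame) for ch, t in acc.items()}

    # candidate links within the radius, via KD-trees per channel pair
    links: list[tuple[float, str, int, str, int]] = []
    for ch_a, ch_b in itertools.combinations(channels, 2):
        if not len(coords[ch_a]) or not len(coords[ch_b]):
            continue
        tree = cKDTree(coords[ch_b])
        pairs = cKDTree(coords[ch_a]).query_ball_tree(tree, r=params.coloc_radius)
        for i, js in enumerate(pairs):
            for j in js:
                d = float(np.linalg.norm(coords[ch_a][i] - coords[ch_b][j]))
                if d <= params.coloc_radius:
                    links.append((d, ch_a, i, ch_b, j))
    links.sort(key=lambda t: (t[0], t[1], t[2], t[3], t[4]))

    assignment: dict[tuple[str, int], ColocRecord] = {}
    records: list[ColocRecord] = []
    for d, ch_a, i, ch_b, j in links:
        key_a, key_b = (ch_a, i), (ch_b, j)
        rec_a, rec_b = assignment.get(key_a), assignment.get(key_b)
        if rec_a is not None and rec_b is not None:
            continue
        if rec_a is None and rec_b is None:
            rec = ColocRecord(members=[key_a, key_b], distances={(ch_a, ch_b): d})
            records.append(rec)
            assignment[key_a] = assignment[key_b] = rec
            continue
        rec, newcomer, new_ch = ((rec_a, key_b, ch_b) if rec_a is not None
                                 else (rec_b, key_a, ch_a))
        if new_ch in rec.channels or len(rec.members) >= 3:
            continue
        if params.triple_rule == "clique":
            ok = all(
                float(np.linalg.norm(coords[new_ch][newcomer[1]] - coords[m_ch][m_i]))
                <= params.coloc_radius
                for m_ch, m_i in rec.members
            )
        else:  # chain rule: proximity to one member suffices
            ok = True
        if not ok:
            continue
        for m_ch, m_i in rec.members:
            dd = float(np.linalg.norm(coords[new_ch][newcomer[1]] - coords[m_ch][m_i]))
            rec.distances[tuple(sorted((new_ch, m_ch)))] = dd  # type: ignore[index]
        rec.members.append(newcomer)
        assignment[newcomer] = rec

    for ch in channels:
        for i in range(len(acc[ch])):
            if (ch, i) not in assignment:
                rec = ColocRecord(members=[(ch, i)], distances={})
                records.append(rec)
                assignment[(ch, i)] = rec

    summary = _summarize(records, {ch: len(acc[ch]) for ch in channels})
    for ch in channels:
        row = summary.loc[ch]
        double_cols = [c for c in summary.columns if c.startswith("double:")]
        conserved = row["single"] + row[double_cols].sum() + row["triple"]
        assert conserved == row["total"], (
            f"conservation violated for channel {ch}: {conserved} != {row['total']}"
        )
    return records, summary


def _summarize(records: Sequence[ColocRecord], totals: Mapping[str, int]) -> pd.DataFrame:
    channels = sorted(totals)
    double_cols = [f"double:{a},{b}" for a, b in itertools.combinations(channels, 2)]
    summary = pd.DataFrame(0, index=pd.Index(channels, name="channel"),
                           columns=["total", "single", *double_cols, "triple"])
    summary["total"] = [totals[ch] for ch in channels]
    for rec in records:
        for ch, _ in rec.members:
            summary.loc[ch, rec.label] += 1
    return summary


def coloc_fraction(summary_or_records, channel: str,
                   partner_spec: Sequence[str]) -> float:
    """Fraction of a channel's spots co-localized with all listed partners.

    E.g. ``coloc_fraction(records, "red", ["green"])`` is the fraction of red
    spots found in a record that also contains a green spot (doubles or
    triples).  A zero spot total yields NaN (missing), never 0.
    """
    records: Sequence[ColocRecord] = summary_or_records
    partners = set(partner_spec)
    total = sum(1 for r in records for ch, _ in r.members if ch == channel)
    if total == 0:
        warnings.warn(f"no spots in channel {channel}; fraction undefined", stacklevel=2)
        return float("nan")
    hits = sum(
        1
        for r in records
        for ch, _ in r.members
        if ch == channel and partners <= (r.channels - {channel})
    )
    return hits / total


# ---------------------------------------------------------------------------
# random-chance expectation


def _pair_within(points_a: np.ndarray, points_b: np.ndarray, radius: float,
                 frame: str) -> np.ndarray:
    delta = points_a - points_b
    if frame == "2d":
        delta = delta[:, 1:]  # drop z
    return np.linalg.norm(delta, axis=1) <= radius


def expected_random_coloc(counts: Mapping[str, int], n_cells: int,
                          params: ColocParams | None = None,
                          n_mc: int = 100_000, n_null: int = 1000,
                          interval: float = 0.99,
                          seed: int | np.random.Generator = 0) -> dict:
    """Expected doubles/triples if genes burst independently of each other.

    ``counts`` maps channel label to the number of detected nascent spots
    (one spot per active cell assumed).  Two expectations are returned:

    * ``model_a``: cell-level independence only — the expected number of
      cells active for a pair (``n_A n_B / C``) or all three
      (``n_A n_B n_C / C^2``);
    * ``model_b``: model (a) times the geometric probability that points
      placed independently and uniformly in a nuclear sphere fall within the
      co-localization radius (pairwise, and all-pairwise for triples),
      estimated by Monte Carlo with its standard error.

    ``model_b`` additionally carries a central predictive interval for the
    observed count under the null, from ``n_null`` hierarchical simulations
    (hypergeometric cell overlap, then binomial thinning by the geometric
    probability).  The interval is what an observed count should be compared
    against; default coverage 0.99.
    """
    if params is None:
        params = ColocParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    channels = sorted(counts)
    for ch in channels:
        if counts[ch] < 0:
            raise ValueError("spot counts must be non-negative")
        if counts[ch] > 2 * n_cells:
            warnings.warn(
                f"channel {ch}: {counts[ch]} spots exceeds two alleles per cell",
                stacklevel=2,
            )

    # geometric probabilities by Monte Carlo
    R, r = params.nuclear_radius, params.coloc_radius
    pts = [_uniform_ball(rng, n_mc, R) for _ in range(3)]
    within_ab = _pair_within(pts[0], pts[1], r, params.frame)
    p_s = float(within_ab.mean())
    p_s_se = float(np.sqrt(max(p_s * (1 - p_s), 1e-30) / n_mc))
    within_ac = _pair_within(pts[0], pts[2], r, params.frame)
    within_bc = _pair_within(pts[1], pts[2], r, params.frame)
    if params.triple_rule == "clique":
        all3 = within_ab & within_ac & within_bc
    else:
        all3 = within_ab & (within_ac | within_bc)
    p_t = float(all3.mean())
    p_t_se = float(np.sqrt(max(p_t * (1 - p_t), 1e-30) / n_mc))

    model_a: dict[str, float] = {}
    model_b: dict[str, dict] = {}
    q_lo, q_hi = 100 * (1 - interval) / 2, 100 * (1 + interval) / 2
    # the null simulation draws cells, so channel occupancy caps at n_cells
    occ = {ch: min(counts[ch], n_cells) for ch in channels}
    for ch_a, ch_b in itertools.combinations(channels, 2):
        n_a, n_b = counts[ch_a], counts[ch_b]
        exp_a = n_a * n_b / n_cells
        key = f"double:{ch_a},{ch_b}"
        model_a[key] = exp_a
        o_a, o_b = occ[ch_a], occ[ch_b]
        overlap = rng.hypergeometric(o_a, n_cells - o_a, o_b, size=n_null) if min(o_a, o_b) else np.zeros(n_null, int)
        null_counts = rng.binomial(overlap, p_s)
        model_b[key] = dict(
            expected=exp_a * p_s,
            interval=[float(np.percentile(null_counts, q_lo)),
                      float(np.percentile(null_counts, q_hi))],
        )
    if len(channels) >= 3:
        n_a, n_b, n_c = (counts[ch] for ch in channels[:3])
        exp_a3 = n_a * n_b * n_c / n_cells ** 2
        model_a["triple"] = exp_a3
        o_a, o_b, o_c = (occ[ch] for ch in channels[:3])
        ov_ab = rng.hypergeometric(o_a, n_cells - o_a, o_b, size=n_null) if min(o_a, o_b) else np.zeros(n_null, int)
        ov_abc = rng.hypergeometric(ov_ab, n_cells - ov_ab, o_c) if o_c else np.zeros(n_null, int)
        null3 = rng.binomial(ov_abc, p_t)
        model_b["triple"] = dict(
            expected=exp_a3 * p_t,
            interval=[float(np.percentile(null3, q_lo)),
                      float(np.percentile(null3, q_hi))],
        )
    return dict(model_a=model_a, model_b=model_b,
                p_pair=p_s, p_pair_se=p_s_se, p_triple=p_t, p_triple_se=p_t_se,
                interval_coverage=interval)


def _uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    u = rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return v * u * radius  # columns (z, y, x) by convention
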
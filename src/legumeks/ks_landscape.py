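"""Ks landscapes: proportional distributions, peak typing, species-pair
summaries and the selection-pressure report.

Within- and between-species Ks values are binned into a proportional
histogram per species pair (the classic Ks proportional plot used to date
duplication events).  Local maxima are typed by their position on the Ks
axis: a peak at low Ks marks a recent whole-genome duplication, peaks in
the mid window mark speciation, and peaks beyond that mark the ancient
pre-speciation duplication.  The species-pair summary reproduces the
median-Ks and lowest-Ks-gene bookkeeping used to rank species closeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BIN_WIDTH = 0.1
DEFAULT_KS_MAX = 2.0
DEFAULT_MIN_PROPORTION = 0.10

#: peak-typing windows on the Ks axis (upper bounds, inclusive)
RECENT_WGD_MAX = 0.15
SPECIATION_MAX = 0.50
ANCIENT_MAX = 0.80

PEAK_TYPES = ("recent_wgd", "speciation", "ancient_duplication", "unassigned")


@dataclass
class KsPeak:
    center: float
    proportion: float
    type: str = "unassigned"


@dataclass
class KsDistribution:
    species_pair: tuple[str, str]
    bin_edges: np.ndarray
    proportions: np.ndarray
    n_pairs: int
    overflow: int = 0

    def __post_init__(self):
        if self.n_pairs > 0:
            total = self.proportions.sum() + self.overflow / self.n_pairs
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError("proportions plus overflow must sum to 1")


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))


def build_distribution(
    rates: pd.DataFrame,
    pair_filter=None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    ks_max: float = DEFAULT_KS_MAX,
    exclude_tandem: bool = True,
) -> KsDistribution:
    """Proportional Ks histogram for the pairs selected by ``pair_filter``.

    ``pair_filter`` is either a species pair tuple (matched unordered
    against the species_a/species_b columns) or a boolean mask function on
    the DataFrame; None keeps everything.  Undefined (saturated) Ks values
    are excluded; values >= ks_max are truncated into the overflow count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    df = rates
    label = ("all", "all")
    if pair_filter is not None:
        if callable(pair_filter):
            df = df[pair_filter(df)]
        else:
            a, b = pair_filter
            label = _pair_key(a, b)
            keys = df.apply(
                lambda r: _pair_key(r["species_a"], r["species_b"]), axis=1
            ) if len(df) else pd.Series(dtype=object)
            df = df[keys == label] if len(df) else df
    if exclude_tandem and "tandem" in df.columns:
        df = df[~df["tandem"].astype(bool)]
    ks = pd.to_numeric(df["Ks"], errors="coerce").dropna().to_numpy() if len(df) else np.array([])

    edges = np.arange(0.0, ks_max + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    in_range = ks[ks < ks_max]
    overflow = int((ks >= ks_max).sum())
    counts, _ = np.histogram(in_range, bins=edges)
    n_pairs = len(ks)
    proportions = counts / n_pairs if n_pairs else np.zeros(n_bins)
    return KsDistribution(
        species_pair=label,
        bin_edges=edges,
        proportions=proportions,
        n_pairs=n_pairs,
        overflow=overflow,
    )


def detect_peaks(
    dist: KsDistribution, min_proportion: float = DEFAULT_MIN_PROPORTION
) -> list[KsPeak]:
    """Local maxima of the proportional histogram.

    A peak is a plateau of equal bins strictly greater than the values on
    both sides (histogram boundaries count as open sides); the peak is
    reported at the lowest-Ks bin of the plateau, so ties resolve toward
    lower Ks.  A plateau spanning the whole histogram (a flat distribution)
    is not a peak.  Peaks below ``min_proportion`` are discarded.
    """
    p = dist.proportions
    n = len(p)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and p[j + 1] == p[i]:
            j += 1
        left_ok = i == 0 or p[i - 1] < p[i]
        right_ok = j == n - 1 or p[j + 1] < p[i]
        spans_all = i == 0 and j == n - 1
        if left_ok and right_ok and not spans_all and p[i] >= min_proportion:
            center = float((dist.bin_edges[i] + dist.bin_edges[i + 1]) / 2.0)
            peaks.append(KsPeak(center=center, proportion=float(p[i])))
        i = j + 1
    return sorted(peaks, key=lambda pk: pk.center)


def assign_peak_type(
    peak: KsPeak,
    recent_wgd_max: float = RECENT_WGD_MAX,
    speciation_max: float = SPECIATION_MAX,
    ancient_max: float = ANCIENT_MAX,
) -> KsPeak:
    """Type a peak by its center: recent WGD, speciation, or ancient
    duplication; anything beyond the ancient window stays unassigned."""
    c = peak.center
    eps = 1e-9  # bin midpoints carry float noise (e.g. 0.15000000000000002)
    if c <= recent_wgd_max + eps:
        peak.type = "recent_wgd"
    elif c <= speciation_max + eps:
        peak.type = "speciation"
    elif c <= ancient_max + eps:
        peak.type = "ancient_duplication"
    else:
        peak.type = "unassigned"
    return peak


def typed_peaks(
    dist: KsDistribution,
    min_proportion: float = DEFAULT_MIN_PROPORTION,
    recent_wgd_max: float = RECENT_WGD_MAX,
    speciation_max: float = SPECIATION_MAX,
    ancient_max: float = ANCIENT_MAX,
) -> list[KsPeak]:
    return [
        assign_peak_type(p, recent_wgd_max, speciation_max, ancient_max)
        for p in detect_peaks(dist, min_proportion)
    ]


# ---------------------------------------------------------------------------
# species-pair summaries


@dataclass
class SpeciesPairSummary:
    species_pair: tuple[str, str]
    ks_median: float | None
    mean_ka_ks: float | None
    n_pairs: int
    n_genes_lowest_ks: int = 0
    n_genes_highest_ks: int = 0


def summarize_species_pairs(rates: pd.DataFrame) -> tuple[list[SpeciesPairSummary], dict]:
    """Per-species-pair Ks medians plus the closest/farthest report.

    ``rates`` must carry species_a/species_b, Ks, ka_ks and, if available,
    relation and tandem columns (from classification).  Medians exclude
    tandem-derived pairs; cross-species medians use ortholog pairs when
    relations are present.  The closest species pair attains the minimum
    ortholog Ks for the most gene families (ties: lower median), the
    farthest attains the maximum for the most families (ties: higher
    median); same-species comparisons are excluded from that report.
    """
    df = rates.copy()
    species = sorted(set(df["species_a"]) | set(df["species_b"]))
    if len(species) < 2:
        raise ValueError("need at least two species")
    df["pair"] = [
        _pair_key(a, b) for a, b in zip(df["species_a"], df["species_b"])
    ]
    df["Ks"] = pd.to_numeric(df["Ks"], errors="coerce")
    if "tandem" in df.columns:
        nontandem = df[~df["tandem"].astype(bool)]
    else:
        nontandem = df

    summaries = {}
    for pair, group in nontandem.groupby("pair"):
        sub = group
        if "relation" in group.columns and pair[0] != pair[1]:
            ortho = group[group["relation"] == "ortholog"]
            if len(ortho):
                sub = ortho
        ks = sub["Ks"].dropna()
        ratios = pd.to_numeric(group.get("ka_ks"), errors="coerce").dropna()
        summaries[pair] = SpeciesPairSummary(
            species_pair=pair,
            ks_median=float(ks.median()) if len(ks) else None,
            mean_ka_ks=float(ratios.mean()) if len(ratios) else None,
            n_pairs=int(len(group)),
        )

    # per-gene lowest/highest ortholog Ks counting (cross-species only)
    cross = nontandem[nontandem["species_a"] != nontandem["species_b"]]
    if "relation" in cross.columns:
        cross = cross[cross["relation"] == "ortholog"]
    cross = cross.dropna(subset=["Ks"])
    if "family" in cross.columns and len(cross):
        for fam, group in cross.groupby("family"):
            lo = group.loc[group["Ks"].idxmin(), "pair"]
            hi = group.loc[group["Ks"].idxmax(), "pair"]
            if lo in summaries:
                summaries[lo].n_genes_lowest_ks += 1
            if hi in summaries:
                summaries[hi].n_genes_highest_ks += 1

    cross_pairs = [s for s in summaries.values() if s.species_pair[0] != s.species_pair[1]]
    report: dict = {}
    if cross_pairs:
        closest = max(
            cross_pairs,
            key=lambda s: (s.n_genes_lowest_ks, -(s.ks_median if s.ks_median is not None else np.inf)),
        )
        farthest = max(
            cross_pairs,
            key=lambda s: (s.n_genes_highest_ks, s.ks_median if s.ks_median is not None else -np.inf),
        )
        report = {
            "closest_pair": "-".join(closest.species_pair),
            "closest_n_genes_lowest_ks": closest.n_genes_lowest_ks,
            "farthest_pair": "-".join(farthest.species_pair),
            "farthest_n_genes_highest_ks": farthest.n_genes_highest_ks,
        }
    return sorted(summaries.values(), key=lambda s: s.species_pair), report


# ---------------------------------------------------------------------------
# selection pressure


def selection_pressure_summary(
    rates: pd.DataFrame,
    strong_negative_below: float = 0.3,
) -> dict:
    """Per-gene mean Ka/Ks with selection categories and the global mean.

    Categories: ``strong_negative`` below ``strong_negative_below``,
    ``negative`` below 1, ``positive`` above 1 (``neutral`` at exactly 1).
    The global mean averages the per-gene means, so every gene family
    contributes equally regardless of its pair count.
    """
    df = rates.copy()
    df["ka_ks"] = pd.to_numeric(df["ka_ks"], errors="coerce")
    defined = df.dropna(subset=["ka_ks"])
    if defined.empty:
        raise ValueError("no defined Ka/Ks ratios")

    def categorize(mean: float) -> str:
        if mean < strong_negative_below:
            return "strong_negative"
        if mean < 1.0:
            return "negative"
        if mean > 1.0:
            return "positive"
        return "neutral"

    per_gene = {}
    if "family" in defined.columns:
        for fam, group in defined.groupby("family"):
            mean = float(group["ka_ks"].mean())
            per_gene[fam] = {"mean_ka_ks": mean, "category": categorize(mean)}
        global_mean = float(np.mean([g["mean_ka_ks"] for g in per_gene.values()]))
    else:
        global_mean = float(defined["ka_ks"].mean())
        per_gene["all"] = {
            "mean_ka_ks": global_mean,
            "category": categorize(global_mean),
        }
    return {
        "global_mean_ka_ks": global_mean,
        "global_category": categorize(global_mean),
        "per_gene": per_gene,
    }


# ---------------------------------------------------------------------------
# output


def distribution_table(dists: list[KsDistribution]) -> pd.DataFrame:
    rows = []
    for dist in dists:
        pair = "-".join(dist.species_pair)
        for i, prop in enumerate(dist.proportions):
            rows.append(
                {
                    "pair": pair,
                    "bin_start": float(dist.bin_edges[i]),
                    "bin_end": float(dist.bin_edges[i + 1]),
                    "proportion": float(prop),
                    "n": dist.n_pairs,
                }
            )
    return pd.DataFrame(rows)


def peaks_table(peaks_by_pair: dict[tuple[str, str], list[KsPeak]]) -> pd.DataFrame:
    rows = []
    for pair, peaks in sorted(peaks_by_pair.items()):
        for pk in peaks:
            rows.append(
                {
                    "pair": "-".join(pair),
                    "center": pk.center,
                    "proportion": pk.proportion,
                    "type": pk.type,
                }
            )
    return pd.DataFrame(rows, columns=["pair", "center", "proportion", "type"])


def plot_distributions(dists: list[KsDistribution], path) -> None:
    """Proportional line plot of Ks distributions (one line per pair)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for dist in dists:
        centers = (dist.bin_edges[:-1] + dist.bin_edges[1:]) / 2.0
        ax.plot(centers, dist.proportions, marker="o", markersize=3,
                label="-".join(dist.species_pair))
    ax.set_xlabel("Ks")
    ax.set_ylabel("proportion of pairs")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
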
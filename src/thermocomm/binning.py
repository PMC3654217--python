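"""Composition-based population binning of assembled contigs.

Contigs from one organism population share a nucleotide word frequency
(NWF) signature and a G+C content; contigs above a length cutoff are
described by canonical k-mer frequency vectors (both strands pooled), the
vectors are ordinated by PCA, clustered into population bins, and each bin
is screened against G+C and taxon-label outliers. Bin summaries and a
single-copy marker survey proxy genome completeness and contamination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from ._seq import BASES, encode
from .ordination import PcaResult, pca

__all__ = [
    "CompositionVectors",
    "BinAssignment",
    "canonical_kmers",
    "composition_vectors",
    "pca_composition",
    "cluster_composition",
    "screen_bins",
    "summarize_bins",
    "survey_single_copy",
]

KEPT = "kept"
DROPPED_GC = "dropped-gc"
DROPPED_TAXON = "dropped-taxon"


def canonical_kmers(k: int) -> tuple[list[str], np.ndarray]:
    """Sorted canonical k-mers and the map word-index -> canonical column.

    The canonical form of a word is the lexicographic minimum of the word
    and its reverse complement; at k=4 there are 136 canonical words.
    """
    words = ["".join(p) for p in product(BASES, repeat=k)]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    canon = []
    for w in words:
        rc = "".join(comp[c] for c in reversed(w))
        canon.append(min(w, rc))
    uniq = sorted(set(canon))
    col = {w: i for i, w in enumerate(uniq)}
    return uniq, np.array([col[c] for c in canon], dtype=np.int64)


def _word_counts(codes: np.ndarray, k: int) -> np.ndarray:
    """Counts over all 4**k words; windows containing ambiguity are skipped."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(4**k, dtype=np.int64)
    idx = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        bad |= c < 0
        idx = (idx << 2) | np.where(c < 0, 0, c).astype(np.int64)
    return np.bincount(idx[~bad], minlength=4**k)


@dataclass
class CompositionVectors:
    """Canonical word frequency vectors plus per-contig length and G+C."""

    freqs: pd.DataFrame  # contigs x canonical words, rows sum to 1
    meta: pd.DataFrame  # index contig id; columns length, gc


def composition_vectors(contigs, k: int = 4, min_len: int = 5000) -> CompositionVectors:
    """Canonical k-mer frequency vectors for contigs >= ``min_len`` bp."""
    if not 2 <= k <= 6:
        raise ValueError("k must be in [2, 6]")
    if min_len < 1000:
        raise ValueError("min_len must be >= 1000")
    cols, canon_map = canonical_kmers(k)
    rows, meta_rows, ids = [], [], []
    for rec in contigs:
        seq = str(rec.seq).upper()
        if len(seq) < min_len:
            continue
        codes = encode(seq)
        counts = _word_counts(codes, k)
        pooled = np.bincount(canon_map, weights=counts, minlength=len(cols))
        total = pooled.sum()
        if total == 0:
            warnings.warn(f"contig {rec.id} has no valid {k}-mer window; excluded")
            continue
        rows.append(pooled / total)
        n_gc = int(((codes == 1) | (codes == 2)).sum())
        n_ok = int((codes >= 0).sum())
        meta_rows.append((len(seq), n_gc / n_ok if n_ok else np.nan))
        ids.append(rec.id)
    freqs = pd.DataFrame(rows, index=ids, columns=cols)
    meta = pd.DataFrame(meta_rows, index=ids, columns=["length", "gc"])
    return CompositionVectors(freqs=freqs, meta=meta)


def pca_composition(vectors: CompositionVectors, center: bool = True,
                    scale: bool = False) -> PcaResult:
    """PCA of the word-frequency matrix (deterministic sign convention)."""
    return pca(vectors.freqs, center=center, scale=scale)


@dataclass
class BinAssignment:
    """Contig -> bin table with screening flags.

    ``assign`` has columns (contig_id, bin, flag); flags are ``kept``,
    ``dropped-gc`` or ``dropped-taxon``. ``anchors`` optionally labels each
    bin with its majority taxon.
    """

    assign: pd.DataFrame
    anchors: dict[str, str] = field(default_factory=dict)

    def kept(self) -> pd.DataFrame:
        return self.assign[self.assign["flag"] == KEPT]


def cluster_composition(
    pca_result: PcaResult,
    gc: pd.Series,
    n_bins: int | str = "auto",
    seed: int = 0,
) -> BinAssignment:
    """K-means population binning on leading components plus G+C.

    Features are the first D principal components (smallest D reaching 80%
    cumulative variance, minimum 2) and the contig G+C fraction, each
    standardized to unit variance so compositional signal and G+C weigh in
    together. ``n_bins="auto"`` picks the cluster number in 2..12 by the
    best mean silhouette. Bins are relabelled by ascending mean G+C so the
    output is deterministic.
    """
    ids = pca_result.ids
    gc = gc.loc[ids]
    cum = np.cumsum(pca_result.explained_variance_ratio)
    d = max(2, int(np.searchsorted(cum, 0.8) + 1))
    d = min(d, pca_result.scores.shape[1])
    feats = np.column_stack([pca_result.scores[:, :d], gc.to_numpy(dtype=float)])
    sd = feats.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    feats = (feats - feats.mean(axis=0)) / sd

    n = len(ids)
    if isinstance(n_bins, str):
        best_k, best_sil = 2, -np.inf
        for k in range(2, min(12, n - 1) + 1):
            labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(feats)
            sil = silhouette_score(feats, labels)
            if sil > best_sil + 1e-12:
                best_k, best_sil = k, sil
        n_bins = best_k
    if n_bins > n:
        raise ValueError("fewer contigs than requested bins")
    if n_bins == 1:
        labels = np.zeros(n, dtype=int)
    else:
        labels = KMeans(n_clusters=n_bins, n_init=10, random_state=seed).fit_predict(feats)
    order = (
        pd.DataFrame({"label": labels, "gc": gc.to_numpy()})
        .groupby("label")["gc"].mean().sort_values().index
    )
    relabel = {old: f"bin{i:02d}" for i, old in enumerate(order)}
    assign = pd.DataFrame(
        {"contig_id": ids, "bin": [relabel[l] for l in labels], "flag": KEPT}
    )
    return BinAssignment(assign=assign)


def screen_bins(
    assignment: BinAssignment,
    meta: pd.DataFrame,
    taxon_labels: pd.Series | None = None,
    gc_threshold: float = 0.05,
) -> BinAssignment:
    """Flag contigs that conflict with their bin's G+C or majority taxon.

    A contig is dropped when its G+C deviates from the bin's length-weighted
    mean by more than ``gc_threshold``, or (when labels are supplied) when
    its taxon label disagrees with the bin's majority label. Dropped contigs
    keep their bin column but are flagged, never reassigned.
    """
    df = assignment.assign.merge(meta, left_on="contig_id", right_index=True)
    flags = {}
    anchors = {}
    for bin_id, grp in df[df["flag"] == KEPT].groupby("bin"):
        wmean = np.average(grp["gc"], weights=grp["length"])
        majority = None
        if taxon_labels is not None:
            labs = taxon_labels.reindex(grp["contig_id"]).dropna()
            if len(labs):
                majority = labs.value_counts().sort_index().idxmax()
                anchors[bin_id] = majority
        for row in grp.itertuples():
            if abs(row.gc - wmean) > gc_threshold:
                flags[row.contig_id] = DROPPED_GC
            elif majority is not None:
                lab = taxon_labels.get(row.contig_id)
                if lab is not None and not pd.isna(lab) and lab != majority:
                    flags[row.contig_id] = DROPPED_TAXON
    out = assignment.assign.copy()
    out["flag"] = [flags.get(c, f) for c, f in zip(out["contig_id"], out["flag"])]
    return BinAssignment(assign=out, anchors=anchors)


def summarize_bins(assignment: BinAssignment, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-bin summary: scaffold count, total Mbp, largest kbp, mean G+C %.

    The G+C mean is length-weighted; empty bins are omitted with a warning.
    """
    kept = assignment.kept().merge(meta, left_on="contig_id", right_index=True)
    all_bins = set(assignment.assign["bin"])
    rows = []
    for bin_id, grp in kept.groupby("bin"):
        rows.append(dict(
            bin=bin_id,
            n_scaffolds=len(grp),
            total_mbp=grp["length"].sum() / 1e6,
            largest_kbp=grp["length"].max() / 1e3,
            mean_gc_pct=100.0 * np.average(grp["gc"], weights=grp["length"]),
            dominant_taxon=assignment.anchors.get(bin_id, ""),
        ))
    for bin_id in sorted(all_bins - {r["bin"] for r in rows}):
        warnings.warn(f"bin {bin_id} has no kept contigs; omitted from summary")
    return pd.DataFrame(rows).sort_values("bin").reset_index(drop=True)


@dataclass
class SingleCopySurvey:
    """Marker counts per bin plus completeness/contamination proxies."""

    counts: pd.DataFrame  # bins x markers
    proxies: pd.DataFrame  # bin -> completeness, contamination


def survey_single_copy(
    assignment: BinAssignment,
    annotations: pd.DataFrame,
    markers: list[str],
) -> SingleCopySurvey:
    """Count single-copy marker families per bin.

    Completeness proxy = fraction of markers seen at least once;
    contamination proxy = fraction seen more than once (duplicated markers
    suggest a merged bin).
    """
    if not markers:
        return SingleCopySurvey(counts=pd.DataFrame(), proxies=pd.DataFrame())
    kept = assignment.kept()
    contig_bin = dict(zip(kept["contig_id"], kept["bin"]))
    ann = annotations[annotations["family_id"].isin(markers)].copy()
    ann["bin"] = ann["contig_id"].map(contig_bin)
    ann = ann.dropna(subset=["bin"])
    counts = (
        ann.groupby(["bin", "family_id"]).size().unstack(fill_value=0)
        .reindex(columns=markers, fill_value=0)
        .reindex(index=sorted(set(kept["bin"])), fill_value=0)
    )
    proxies = pd.DataFrame({
        "completeness": (counts >= 1).mean(axis=1),
        "contamination": (counts >= 2).mean(axis=1),
    })
    return SingleCopySurvey(counts=counts, proxies=proxies)
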
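"""CRISPR array detection, direct-repeat census, and spacer-virus linkage.

Arrays are found de novo by seed-and-extend over exact repeated words;
direct repeats (DRs) are censused per sample with a minimum-instance
exclusion; spacers are matched against scaffolds by an exact full-length
gapless Hamming scan at a bounded mismatch count (a deterministic, stricter
stand-in for heuristic word-search alignment); scaffolds are called viral
from a homology hit table; and cross-sample viral scaffolds are grouped by
shared-word nucleotide identity.

All coordinates are 0-based, half-open; minus-strand matches are reported
at their forward-strand start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import canonical, encode, revcomp

__all__ = [
    "CrisprParams",
    "CrisprArray",
    "LinkageReport",
    "find_crispr_arrays",
    "extract_spacers",
    "dr_census",
    "classify_dr",
    "match_spacers",
    "call_viral",
    "linkage_report",
    "viral_group_clustering",
]


@dataclass(frozen=True)
class CrisprParams:
    """Detector acceptance thresholds (CRISPRFinder-style conventions)."""

    dr_min: int = 21
    dr_max: int = 48
    spacer_min_frac: float = 0.6
    spacer_max_frac: float = 2.5
    seed_len: int = 13
    min_units: int = 3
    max_unit_mismatch: int = 2
    max_spacer_identity: float = 0.6  # consecutive spacers must be less similar


@dataclass
class CrisprArray:
    """A detected repeat-spacer locus.

    ``units`` and ``spacers`` are (start, end) interval lists on the contig;
    the consensus is the per-column majority over the repeat units.
    """

    contig: str
    sample: str
    units: list[tuple[int, int]]
    spacers: list[tuple[int, int]]
    consensus: str
    spacer_seqs: list[str] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.units[0][0], self.units[-1][1]

    @property
    def n_units(self) -> int:
        return len(self.units)


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(a[i] == b[i] for i in range(n)) / n


def find_crispr_arrays(
    contig, params: CrisprParams = CrisprParams(), sample: str = ""
) -> list[CrisprArray]:
    """Detect CRISPR arrays in one contig by seed-and-extend.

    Exact repeated words of ``seed_len`` at spacings compatible with one
    repeat period seed candidate arrays; unit boundaries are extended while
    all units agree; candidates are accepted when they have >= ``min_units``
    units, a DR length in [dr_min, dr_max], every unit within
    ``max_unit_mismatch`` of the consensus, spacer lengths within
    [spacer_min_frac, spacer_max_frac] x DR length, and consecutive spacers
    below ``max_spacer_identity`` identical. Overlapping candidates resolve
    to the one with most units, then the leftmost.
    """
    seq = str(contig.seq).upper()
    L = len(seq)
    if L < 200:
        return []
    w = params.seed_len
    period_min = params.dr_min + int(np.ceil(params.spacer_min_frac * params.dr_min))
    period_max = params.dr_max + int(params.spacer_max_frac * params.dr_max)

    positions: dict[str, list[int]] = {}
    for i in range(L - w + 1):
        word = seq[i : i + w]
        if "N" in word:
            continue
        positions.setdefault(word, []).append(i)

    candidates: list[CrisprArray] = []
    for word in sorted(positions):
        pos = positions[word]
        if len(pos) < params.min_units:
            continue
        # maximal runs with gaps compatible with one repeat period
        run = [pos[0]]
        runs = []
        for p in pos[1:]:
            if period_min <= p - run[-1] <= period_max:
                run.append(p)
            else:
                runs.append(run)
                run = [p]
        runs.append(run)
        for chain in runs:
            if len(chain) < params.min_units:
                continue
            arr = _extend_chain(seq, chain, w, params, contig.id, sample)
            if arr is not None:
                candidates.append(arr)

    return _resolve_overlaps(candidates)


def _extend_chain(seq, chain, w, params, contig_id, sample) -> CrisprArray | None:
    min_gap = min(b - a for a, b in zip(chain, chain[1:]))
    max_ext = params.dr_max - w
    # extend left while the column is unanimous across units
    left = 0
    while (left < max_ext and chain[0] - left - 1 >= 0
           and len({seq[p - left - 1] for p in chain}) == 1
           and w + left + 1 <= min_gap):
        left += 1
    right = 0
    while (left + right < max_ext and chain[-1] + w + right < len(seq)
           and len({seq[p + w + right] for p in chain}) == 1
           and w + left + right + 1 <= min_gap):
        right += 1
    unit_len = w + left + right
    if not params.dr_min <= unit_len <= params.dr_max:
        return None
    units = [(p - left, p - left + unit_len) for p in chain]
    unit_seqs = [seq[s:e] for s, e in units]
    consensus = "".join(
        max(set(col), key=lambda c: (col.count(c), c)) for col in zip(*unit_seqs)
    )
    if any(sum(a != b for a, b in zip(u, consensus)) > params.max_unit_mismatch
           for u in unit_seqs):
        return None
    spacers = [(units[i][1], units[i + 1][0]) for i in range(len(units) - 1)]
    sp_seqs = [seq[s:e] for s, e in spacers]
    lo = params.spacer_min_frac * unit_len
    hi = params.spacer_max_frac * unit_len
    if any(not lo <= (e - s) <= hi for s, e in spacers):
        return None
    for a, b in zip(sp_seqs, sp_seqs[1:]):
        if _identity(a, b) >= params.max_spacer_identity:
            return None
    return CrisprArray(contig=contig_id, sample=sample, units=units,
                       spacers=spacers, consensus=consensus, spacer_seqs=sp_seqs)


def _resolve_overlaps(candidates: list[CrisprArray]) -> list[CrisprArray]:
    """Among mutually overlapping candidates keep most units, then leftmost."""
    if not candidates:
        return []
    candidates = sorted(candidates, key=lambda a: (a.span[0], -a.n_units))
    kept: list[CrisprArray] = []
    for cand in sorted(candidates, key=lambda a: (-a.n_units, a.span[0])):
        s, e = cand.span
        if all(e <= k.span[0] or s >= k.span[1] for k in kept):
            kept.append(cand)
    return sorted(kept, key=lambda a: a.span[0])


def extract_spacers(arrays: list[CrisprArray]) -> pd.DataFrame:
    """Flatten arrays into a spacer table for matching.

    Columns: spacer_id (sample, array, ordinal), sequence, and the source
    locus (contig, start, end) used for self-match masking.
    """
    rows = []
    for ai, arr in enumerate(arrays):
        for si, ((s, e), sp) in enumerate(zip(arr.spacers, arr.spacer_seqs)):
            rows.append(dict(
                spacer_id=f"{arr.sample}|{arr.contig}|arr{ai}|sp{si}",
                sequence=sp, source_contig=arr.contig,
                source_start=arr.span[0], source_end=arr.span[1],
            ))
    return pd.DataFrame(rows, columns=["spacer_id", "sequence", "source_contig",
                                       "source_start", "source_end"])


def dr_census(arrays: list[CrisprArray], min_instances: int = 10) -> pd.DataFrame:
    """Census of direct-repeat families in one sample.

    Families are exact strand-canonicalized consensus sequences; the
    instance count is the total number of repeat units across arrays.
    Families with fewer than ``min_instances`` units are excluded.
    """
    counts: dict[str, list[int]] = {}
    for arr in arrays:
        fam = canonical(arr.consensus)
        counts.setdefault(fam, [0, 0])
        counts[fam][0] += arr.n_units
        counts[fam][1] += 1
    rows = [dict(consensus=fam, n_units=c[0], n_arrays=c[1])
            for fam, c in sorted(counts.items()) if c[0] >= min_instances]
    return pd.DataFrame(rows, columns=["consensus", "n_units", "n_arrays"])


def _edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (sequences here are <= 48 bp)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def classify_dr(
    census: pd.DataFrame,
    reference: list,
    max_distance_frac: float = 0.25,
) -> pd.DataFrame:
    """Label DR families with the nearest reference repeat's taxon.

    Both orientations are tried; a family is unclassified when the minimum
    edit distance exceeds ``max_distance_frac`` of its length. Distance ties
    go to the lexicographically smallest taxon label and are flagged.
    """
    if not len(reference):
        raise ValueError("reference DR set must be non-empty")
    refs = []
    for rec in reference:
        taxon = rec.id
        for tokenn in str(rec.description).split():
            if tokenn.startswith("taxon="):
                taxon = tokenn[6:]
        refs.append((taxon, str(rec.seq).upper()))
    out = census.copy()
    labels, dists, ties = [], [], []
    for fam in out["consensus"]:
        best = []
        for taxon, rseq in refs:
            d = min(_edit_distance(fam, rseq), _edit_distance(fam, revcomp(rseq)))
            best.append((d, taxon))
        dmin = min(d for d, _ in best)
        cands = sorted(t for d, t in best if d == dmin)
        if dmin > max_distance_frac * len(fam):
            labels.append("unclassified")
            ties.append(False)
        else:
            labels.append(cands[0])
            ties.append(len(cands) > 1)
        dists.append(dmin)
    out["taxon"] = labels
    out["distance"] = dists
    out["tie"] = ties
    return out


def match_spacers(
    spacers: pd.DataFrame,
    scaffolds: list,
    max_mismatch: int = 3,
    mask_sources: bool = True,
) -> pd.DataFrame:
    """Exact full-length gapless Hamming scan of spacers against scaffolds.

    Every position on both strands of every scaffold with at most
    ``max_mismatch`` substitutions is reported; ambiguity codes in the
    scaffold count as mismatches to everything. When ``mask_sources`` is
    set, matches overlapping the spacer's own source array are suppressed.
    Minus-strand starts are forward-strand coordinates.
    """
    if len(spacers) and (spacers["sequence"].str.len() < 18).any():
        raise ValueError("spacers must be >= 18 bp")
    scaffold_codes = {rec.id: encode(str(rec.seq).upper()) for rec in scaffolds}
    rows = []
    for sp in spacers.itertuples(index=False):
        fwd = encode(sp.sequence)
        rev = encode(revcomp(sp.sequence))
        m = len(fwd)
        for sid, codes in scaffold_codes.items():
            if len(codes) < m:
                continue
            win = sliding_window_view(codes, m)
            for strand, query in (("+", fwd), ("-", rev)):
                mm = m - (win == query).sum(axis=1)
                for start in np.nonzero(mm <= max_mismatch)[0]:
                    start = int(start)
                    if (mask_sources and sid == sp.source_contig
                            and start < sp.source_end and start + m > sp.source_start):
                        continue
                    rows.append(dict(spacer_id=sp.spacer_id, target=sid,
                                     start=start, strand=strand,
                                     mismatches=int(mm[start])))
    return pd.DataFrame(rows, columns=["spacer_id", "target", "start",
                                       "strand", "mismatches"])


def call_viral(
    scaffold_ids: list[str],
    hit_table: pd.DataFrame | None = None,
    truth_labels: dict[str, bool] | None = None,
    e_threshold: float = 1e-5,
) -> pd.DataFrame:
    """Call scaffolds viral from homology evidence (or planted truth labels).

    Hit-table mode: a scaffold is viral iff its best hit against the viral
    reference has E <= ``e_threshold``. Scaffolds without evidence are
    non-viral with a ``no-evidence`` note.
    """
    rows = []
    if truth_labels is not None:
        for sid in scaffold_ids:
            rows.append(dict(contig_id=sid, is_viral=bool(truth_labels.get(sid, False)),
                             evidence="truth", note=""))
    elif hit_table is not None:
        best = hit_table.groupby("qseqid")["evalue"].min()
        for sid in scaffold_ids:
            if sid in best.index:
                e = float(best[sid])
                rows.append(dict(contig_id=sid, is_viral=e <= e_threshold,
                                 evidence=f"best-hit E={e:g}", note=""))
            else:
                rows.append(dict(contig_id=sid, is_viral=False,
                                 evidence="", note="no-evidence"))
    else:
        raise ValueError("either hit_table or truth_labels must be given")
    return pd.DataFrame(rows)


@dataclass
class LinkageReport:
    """Spacer-to-scaffold linkage summary across a sample set."""

    total_spacers: int
    spacers_viral_le1: int
    spacers_viral_le3: int
    spacers_nonviral: int
    viral_hit: int
    viral_total: int

    def __post_init__(self) -> None:
        assert self.spacers_viral_le1 <= self.spacers_viral_le3 <= self.total_spacers


def linkage_report(
    matches_k1: pd.DataFrame,
    matches_k3: pd.DataFrame,
    calls: pd.DataFrame,
    spacers: pd.DataFrame,
) -> LinkageReport:
    """Summarize spacer matches against viral and non-viral scaffolds.

    ``matches_k1``/``matches_k3`` must come from the same inputs at
    max_mismatch 1 and 3. Spacer counts are distinct spacers with at least
    one qualifying match.
    """
    viral = set(calls[calls["is_viral"]]["contig_id"])
    n_le1 = matches_k1[matches_k1["target"].isin(viral)]["spacer_id"].nunique() \
        if len(matches_k1) else 0
    n_le3 = matches_k3[matches_k3["target"].isin(viral)]["spacer_id"].nunique() \
        if len(matches_k3) else 0
    n_nonviral = matches_k3[~matches_k3["target"].isin(viral)]["spacer_id"].nunique() \
        if len(matches_k3) else 0
    hit_viral = matches_k3[matches_k3["target"].isin(viral)]["target"].nunique() \
        if len(matches_k3) else 0
    return LinkageReport(
        total_spacers=len(spacers),
        spacers_viral_le1=int(n_le1),
        spacers_viral_le3=int(n_le3),
        spacers_nonviral=int(n_nonviral),
        viral_hit=int(hit_viral),
        viral_total=int(calls["is_viral"].sum()),
    )


def _pair_identity(a: str, b: str, word: int = 16) -> float:
    """Nucleotide identity by shared-word anchoring on the best diagonal."""
    index: dict[str, list[int]] = {}
    for i in range(len(a) - word + 1):
        index.setdefault(a[i : i + word], []).append(i)
    diagonals: dict[int, list[int]] = {}
    for j in range(len(b) - word + 1):
        for i in index.get(b[j : j + word], ()):
            diagonals.setdefault(j - i, []).append(i)
    if not diagonals:
        return 0.0
    diag = max(diagonals, key=lambda d: (len(diagonals[d]), -abs(d)))
    anchors = diagonals[diag]
    lo, hi = min(anchors), max(anchors) + word
    lo = max(lo, -diag if diag < 0 else 0)
    hi = min(hi, len(a), len(b) - diag)
    if hi <= lo:
        return 0.0
    matches = sum(a[i] == b[i + diag] for i in range(lo, hi))
    return matches / (hi - lo)


def viral_group_clustering(
    scaffolds: list,
    min_identity: float = 0.92,
    word: int = 16,
) -> list[list[str]]:
    """Single-linkage groups of viral scaffolds at a nucleotide identity cutoff.

    Pairwise identity is estimated by exact shared words of length ``word``
    chained along the dominant diagonal with ungapped comparison over the
    anchored span; unrelated scaffolds (no shared word) stay singletons.
    """
    if len(scaffolds) < 2:
        return [[rec.id] for rec in scaffolds]
    ids = [rec.id for rec in scaffolds]
    seqs = [str(rec.seq).upper() for rec in scaffolds]
    parent = list(range(len(ids)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ident = max(_pair_identity(seqs[i], seqs[j], word),
                        _pair_identity(seqs[i], revcomp(seqs[j]), word))
            if ident >= min_identity:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i, sid in enumerate(ids):
        groups.setdefault(find(i), []).append(sid)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])
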
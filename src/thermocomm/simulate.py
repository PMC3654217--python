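"""Synthetic multi-site metagenome communities with machine-readable truth.

Emulates the statistical structure of archaeal-dominated hot-spring
metagenomes: several co-occurring populations distinguishable by G+C
content and nucleotide word frequencies, CRISPR arrays whose spacers hit
planted viral scaffolds at a controlled number of mismatches, Sanger-scale
shotgun reads, assembly-like contigs, and per-site functional-category
gene profiles. Every planted feature is recorded in truth tables so each
downstream analysis stage can be scored against ground truth.

Genome model
------------
Each population genome is an order-k Markov chain (k = 0..3). The next-base
distribution of every context starts from the G+C-tilted base composition
and is perturbed multiplicatively by a population-specific seeded factor,
then renormalized *within* the {G,C} and {A,T} groups so that the G+C mass
of every context equals the target exactly. Realized G+C is therefore
Binomial(L, gc_target)/L — tightly controlled — while word frequencies
carry a population signature that composition-based binning can separate.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.stats import truncnorm

from ._rng import derive_rng, derive_seed
from ._seq import BASES, decode, random_dna, revcomp

__all__ = [
    "PopulationSpec",
    "ViralElementSpec",
    "CrisprArraySpec",
    "SiteSpec",
    "CommunityTruth",
    "generate_population_genome",
    "plant_crispr_and_viruses",
    "shred_reads",
    "shred_contigs",
    "synthesize_annotations",
    "write_community",
    "default_community",
    "synthesize_marker_tables",
]

READ_LEN_MIN = 200
READ_LEN_MAX = 2000


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class PopulationSpec:
    """One source population: a genome with controlled G+C and word signature.

    ``taxon_path`` is an ordered list of (rank, name) pairs from domain down
    to genus, used to label reads/contigs in truth tables and to build the
    reference taxonomy for read profiling.
    """

    name: str
    genome_length: int
    gc_target: float
    markov_order: int = 2
    signature_seed: int = 0
    abundance_weight: float = 1.0
    taxon_path: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.genome_length < 50_000:
            raise ValueError("genome_length must be >= 50,000 bp")
        if not 0.2 <= self.gc_target <= 0.75:
            raise ValueError("gc_target must lie in [0.2, 0.75]")
        if not 0 <= self.markov_order <= 3:
            raise ValueError("markov_order must be 0..3")


@dataclass(frozen=True)
class ViralElementSpec:
    """A viral scaffold planted into the community."""

    id: str
    length: int
    sites_present: tuple[str, ...] = ()
    gc: float = 0.45

    def __post_init__(self) -> None:
        if not 5_000 <= self.length <= 70_000:
            raise ValueError("viral element length must be in [5000, 70000] bp")


@dataclass(frozen=True)
class CrisprArraySpec:
    """A repeat-spacer locus planted into a host genome.

    ``links`` lists (viral id, planted mismatches 0-3) pairs; each link is
    realized by copying one spacer into the viral element with exactly that
    many substitutions. ``decoy_fraction`` of the spacers are guaranteed to
    match nothing.
    """

    host: str
    dr_length: int = 30
    n_units: int = 5
    spacer_length: int = 36
    links: tuple[tuple[str, int], ...] = ()
    decoy_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 21 <= self.dr_length <= 48:
            raise ValueError("dr_length must be in [21, 48]")
        if self.n_units < 3:
            raise ValueError("n_units must be >= 3")
        if not 20 <= self.spacer_length <= 60:
            raise ValueError("spacer_length must be in [20, 60]")
        for _, mm in self.links:
            if not 0 <= mm <= 3:
                raise ValueError("planted mismatches must be 0..3")
        n_spacers = self.n_units - 1
        n_decoy = int(round(self.decoy_fraction * n_spacers))
        if len(self.links) > n_spacers - n_decoy:
            raise ValueError("more links than non-decoy spacers")


@dataclass(frozen=True)
class SiteSpec:
    """One sampling site: population mixture, read depth, functional profile."""

    site: str
    population_weights: dict[str, float]
    category_profile: dict[str, float]
    n_reads: int = 1000
    mean_read_len: int = 800
    sd_read_len: int = 120
    contig_length_law: tuple[int, int, float] = (5_000, 20_000, 1.0)

    def __post_init__(self) -> None:
        if min(self.population_weights.values()) < 0 or max(self.population_weights.values()) <= 0:
            raise ValueError("population weights must be non-negative, at least one positive")
        if self.category_profile and abs(sum(self.category_profile.values()) - 1.0) > 1e-9:
            raise ValueError("category_profile must sum to 1")


@dataclass
class CommunityTruth:
    """Planted ground truth, one table per downstream recovery test.

    All coordinates are 0-based, half-open. ``arrays`` holds one row per
    repeat unit / spacer element; ``spacer_links`` one row per spacer with
    its planted viral target (empty target for decoys / unlinked spacers).
    """

    reads: pd.DataFrame = field(default_factory=pd.DataFrame)
    contigs: pd.DataFrame = field(default_factory=pd.DataFrame)
    arrays: pd.DataFrame = field(default_factory=pd.DataFrame)
    spacer_links: pd.DataFrame = field(default_factory=pd.DataFrame)
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    viral: pd.DataFrame = field(default_factory=pd.DataFrame)

    _FIELDS = ("reads", "contigs", "arrays", "spacer_links", "genes", "viral")

    @classmethod
    def merge(cls, fragments: list["CommunityTruth"]) -> "CommunityTruth":
        out = cls()
        for name in cls._FIELDS:
            parts = [getattr(f, name) for f in fragments if len(getattr(f, name))]
            if parts:
                setattr(out, name, pd.concat(parts, ignore_index=True))
        return out


# ---------------------------------------------------------------------------
# Genome generation


def _transition_cumprobs(spec: PopulationSpec) -> np.ndarray:
    """Per-context cumulative next-base probabilities, G+C mass fixed.

    The multiplicative perturbation is drawn from the population's
    signature seed only, so two populations with equal gc_target but
    different seeds have distinct word statistics.
    """
    gc = spec.gc_target
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    n_ctx = 4**spec.markov_order
    sig = np.random.default_rng(np.random.SeedSequence(spec.signature_seed))
    probs = base * np.exp(0.35 * sig.normal(size=(n_ctx, 4)))
    at = probs[:, [0, 3]]
    gcm = probs[:, [1, 2]]
    probs[:, [0, 3]] = at / at.sum(axis=1, keepdims=True) * (1 - gc)
    probs[:, [1, 2]] = gcm / gcm.sum(axis=1, keepdims=True) * gc
    return np.cumsum(probs, axis=1)


def generate_population_genome(spec: PopulationSpec, seed: int) -> SeqRecord:
    """Sample one population genome from its Markov model.

    Deterministic given (spec, seed); the realized G+C fraction is within
    ±0.015 of ``spec.gc_target`` for genomes >= 100 kb (binomial bound).
    """
    cum = _transition_cumprobs(spec)
    k = spec.markov_order
    rng = derive_rng(seed, "genome", spec.name)
    n = spec.genome_length
    us = rng.random(n).tolist()
    rows = cum.tolist()
    mask = 4**k - 1 if k else 0
    ctx = 0
    out: list[int] = []
    append = out.append
    for u in us:
        row = rows[ctx]
        b = 0 if u < row[0] else 1 if u < row[1] else 2 if u < row[2] else 3
        append(b)
        if k:
            ctx = ((ctx << 2) | b) & mask
    seq = decode(np.array(out, dtype=np.int8))
    return SeqRecord(Seq(seq), id=spec.name, description="")


# ---------------------------------------------------------------------------
# CRISPR arrays and viral elements


def _distinct_spacers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Random spacers, pairwise < 60% identical (rejection-sampled)."""
    spacers: list[str] = []
    while len(spacers) < n:
        cand = random_dna(rng, length)
        ok = all(
            sum(a == b for a, b in zip(cand, s)) < 0.6 * length for s in spacers
        )
        if ok:
            spacers.append(cand)
    return spacers


def _substitute(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    """Exactly n_sub substitutions at distinct positions, never to self."""
    if n_sub == 0:
        return seq
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    chars = list(seq)
    for p in pos:
        alts = [b for b in BASES if b != chars[p]]
        chars[p] = alts[rng.integers(3)]
    return "".join(chars)


def plant_crispr_and_viruses(
    genome: SeqRecord,
    arrays: list[CrisprArraySpec],
    viral_pool: list[ViralElementSpec],
    seed: int,
    viral_seqs: dict[str, str] | None = None,
    occupied_viral: dict[str, list[tuple[int, int]]] | None = None,
) -> tuple[SeqRecord, dict[str, SeqRecord], CommunityTruth]:
    """Write CRISPR arrays into a genome and protospacers into viral elements.

    Each array is ``n_units`` identical direct-repeat copies separated by
    distinct spacers. For every (viral id, m) link one spacer is copied into
    that viral element with exactly m substitutions. Returns the modified
    genome, the viral sequences (shared dict ``viral_seqs`` is updated in
    place so several host genomes can target one pool), and a truth fragment.
    """
    viral_by_id = {v.id: v for v in viral_pool}
    if viral_seqs is None:
        viral_seqs = {}
    for v in viral_pool:
        if v.id not in viral_seqs:
            vrng = derive_rng(seed, "viral", v.id)
            viral_seqs[v.id] = random_dna(vrng, v.length, gc=v.gc)
    if occupied_viral is None:
        occupied_viral = {}
    for v in viral_seqs:
        occupied_viral.setdefault(v, [])

    gseq = list(str(genome.seq))
    placed: list[tuple[int, int]] = []
    array_rows: list[dict] = []
    link_rows: list[dict] = []

    my_arrays = [a for a in arrays if a.host == genome.id]
    for ai, spec in enumerate(my_arrays):
        rng = derive_rng(seed, "array", genome.id, ai)
        for vid, _ in spec.links:
            if vid not in viral_by_id:
                raise ValueError(f"linked viral id {vid!r} not in viral pool")
        dr = random_dna(rng, spec.dr_length)
        n_sp = spec.n_units - 1
        spacers = _distinct_spacers(rng, n_sp, spec.spacer_length)
        array_seq = dr + "".join(s + dr for s in spacers)
        if len(array_seq) > len(gseq):
            raise ValueError("array longer than genome")
        # non-overlapping placement by rejection
        for _ in range(1000):
            start = int(rng.integers(0, len(gseq) - len(array_seq) + 1))
            end = start + len(array_seq)
            if all(end <= s or start >= e for s, e in placed):
                break
        else:
            raise ValueError("could not place array without overlap")
        placed.append((start, end))
        gseq[start:end] = array_seq
        array_id = f"{genome.id}_arr{ai}"
        period = spec.dr_length + spec.spacer_length
        for u in range(spec.n_units):
            us = start + u * period
            array_rows.append(
                dict(contig=genome.id, array_id=array_id, kind="unit",
                     ordinal=u, start=us, end=us + spec.dr_length, sequence=dr)
            )
        n_decoy = int(round(spec.decoy_fraction * n_sp))
        decoy_idx = set(rng.choice(n_sp, size=n_decoy, replace=False).tolist())
        linkable = [i for i in range(n_sp) if i not in decoy_idx]
        link_assign = {linkable[j]: spec.links[j] for j in range(len(spec.links))}
        for si, sp in enumerate(spacers):
            ss = start + spec.dr_length + si * period
            array_rows.append(
                dict(contig=genome.id, array_id=array_id, kind="spacer",
                     ordinal=si, start=ss, end=ss + spec.spacer_length, sequence=sp)
            )
            spacer_id = f"{array_id}_sp{si}"
            row = dict(spacer_id=spacer_id, array_id=array_id, host=genome.id,
                       spacer_seq=sp, viral_id="", planted_mismatches=-1,
                       proto_start=-1, is_decoy=si in decoy_idx)
            if si in link_assign:
                vid, mm = link_assign[si]
                proto = _substitute(rng, sp, mm)
                vseq = viral_seqs[vid]
                for _ in range(1000):
                    ps = int(rng.integers(0, len(vseq) - len(proto) + 1))
                    pe = ps + len(proto)
                    if all(pe <= s or ps >= e for s, e in occupied_viral[vid]):
                        break
                else:
                    raise ValueError("could not place protospacer")
                occupied_viral[vid].append((ps, pe))
                viral_seqs[vid] = vseq[:ps] + proto + vseq[pe:]
                row.update(viral_id=vid, planted_mismatches=mm, proto_start=ps)
            link_rows.append(row)

    truth = CommunityTruth(
        arrays=pd.DataFrame(array_rows),
        spacer_links=pd.DataFrame(link_rows),
        viral=pd.DataFrame(
            [dict(viral_id=v.id, length=v.length,
                  sites_present=",".join(v.sites_present)) for v in viral_pool]
        ),
    )
    new_genome = SeqRecord(Seq("".join(gseq)), id=genome.id, description="")
    viral_records = {
        vid: SeqRecord(Seq(s), id=vid, description="viral") for vid, s in viral_seqs.items()
    }
    return new_genome, viral_records, truth


# ---------------------------------------------------------------------------
# Shredding


def shred_reads(
    genome: SeqRecord,
    n: int,
    mean_len: int,
    sd_len: int,
    seed: int,
    id_prefix: str = "",
    site: str = "",
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Shotgun-read sampler: truncated-normal lengths, uniform position/strand."""
    if n <= 0:
        raise ValueError("n must be positive")
    L = len(genome.seq)
    if mean_len >= L:
        raise ValueError("mean read length must be below genome length")
    rng = derive_rng(seed, "reads", genome.id, id_prefix)
    lo = (READ_LEN_MIN - mean_len) / sd_len
    hi = (min(READ_LEN_MAX, L) - mean_len) / sd_len
    lens = truncnorm.rvs(lo, hi, loc=mean_len, scale=sd_len, size=n, random_state=rng)
    lens = np.round(lens).astype(int)
    gseq = str(genome.seq)
    records, rows = [], []
    for i, rl in enumerate(lens):
        start = int(rng.integers(0, L - rl + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = gseq[start : start + rl]
        if strand == "-":
            frag = revcomp(frag)
        rid = f"{id_prefix}read{i:06d}"
        records.append(SeqRecord(Seq(frag), id=rid, description=""))
        rows.append(dict(read_id=rid, site=site, population=genome.id,
                         start=start, end=start + int(rl), strand=strand))
    return records, pd.DataFrame(rows)


def _draw_lengths(rng: np.random.Generator, law: tuple[int, int, float], n: int) -> np.ndarray:
    lo, hi, shape = int(law[0]), int(law[1]), float(law[2])
    u = rng.random(n) ** shape
    return (lo + u * (hi - lo)).astype(int)


def shred_contigs(
    genome: SeqRecord,
    law: tuple[int, int, float],
    seed: int,
    keep_intact: list[tuple[int, int]] | None = None,
    id_prefix: str = "",
    site: str = "",
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Tile a genome into assembly-like contigs.

    Lengths follow ``law = (min, max, shape)`` (shape 1 = uniform). Segments
    that would split an interval in ``keep_intact`` (planted CRISPR arrays)
    are extended to cover it; a trailing remainder shorter than the minimum
    is merged into the previous contig so the tiling is exhaustive.
    """
    lo, hi, _ = int(law[0]), int(law[1]), law[2]
    L = len(genome.seq)
    if hi > L:
        raise ValueError("law maximum exceeds genome length")
    spans = sorted(keep_intact or [])
    rng = derive_rng(seed, "contigs", genome.id, id_prefix)
    gseq = str(genome.seq)
    bounds: list[tuple[int, int]] = []
    p = 0
    while p < L:
        end = min(p + int(_draw_lengths(rng, law, 1)[0]), L)
        for s, e in spans:
            if s < end < e:  # would split the array: cover it whole
                end = e
        if L - end < lo:
            end = L
        bounds.append((p, end))
        p = end
    if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < lo:
        s0, _ = bounds.pop()
        ps, _ = bounds.pop()
        bounds.append((ps, L))
    records, rows = [], []
    for i, (s, e) in enumerate(bounds):
        cid = f"{id_prefix}{genome.id}_ctg{i:04d}"
        records.append(SeqRecord(Seq(gseq[s:e]), id=cid, description=""))
        rows.append(dict(contig_id=cid, site=site, population=genome.id,
                         genome_start=s, genome_end=e))
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene annotations


def synthesize_annotations(
    contigs: list[SeqRecord],
    site: SiteSpec,
    family_map: dict[str, str],
    seed: int,
) -> pd.DataFrame:
    """Per-contig gene calls with site-specific functional-category mixture.

    Gene density is one gene per kbp; the category of each gene is drawn
    from the site's category profile and the family uniformly within the
    category. Returns columns (gene_id, contig_id, site, family_id,
    category_id, start, end).
    """
    if not contigs:
        raise ValueError("empty contig list")
    if not family_map:
        raise ValueError("family_map must be non-empty")
    cat_to_fams: dict[str, list[str]] = {}
    for fam, cat in sorted(family_map.items()):
        cat_to_fams.setdefault(cat, []).append(fam)
    cats = sorted(site.category_profile)
    for c in cats:
        if c not in cat_to_fams:
            raise ValueError(f"category {c!r} has no families in family_map")
    probs = np.array([site.category_profile[c] for c in cats])
    rng = derive_rng(seed, "genes", site.site)
    rows = []
    for rec in contigs:
        n_genes = len(rec.seq) // 1000
        if n_genes == 0:
            continue
        cat_idx = rng.choice(len(cats), size=n_genes, p=probs)
        for j in range(n_genes):
            cat = cats[cat_idx[j]]
            fams = cat_to_fams[cat]
            fam = fams[rng.integers(len(fams))]
            glen = int(rng.integers(600, 950))
            start = j * 1000 + int(rng.integers(0, 50))
            rows.append(dict(gene_id=f"{rec.id}_g{j:03d}", contig_id=rec.id,
                             site=site.site, family_id=fam, category_id=cat,
                             start=start, end=start + glen))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Community orchestration


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_fasta(records: list[SeqRecord], path: Path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_community(
    sites: list[SiteSpec],
    populations: list[PopulationSpec],
    viral_pool: list[ViralElementSpec],
    out_dir: str | Path,
    seed: int,
    arrays: list[CrisprArraySpec] = (),
    family_map: dict[str, str] | None = None,
) -> dict[str, str]:
    """Generate a full multi-site community and write it to ``out_dir``.

    Emits, per site, read and contig FASTAs; a pooled viral FASTA; a
    reference direct-repeat FASTA labelled with host taxa; TSV truth tables;
    a gene annotation table; and ``manifest.tsv`` (file, sha256). Returns
    the manifest as a dict. Identical (specs, seed) give byte-identical
    files, hence identical checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes: dict[str, SeqRecord] = {}
    truths: list[CommunityTruth] = []
    viral_seqs: dict[str, str] = {}
    occupied: dict[str, list[tuple[int, int]]] = {}
    viral_records: dict[str, SeqRecord] = {}
    dr_refs: list[SeqRecord] = []
    pop_by_name = {p.name: p for p in populations}

    for pop in populations:
        g = generate_population_genome(pop, derive_seed(seed, "pop", pop.name))
        g, viral_records, frag = plant_crispr_and_viruses(
            g, list(arrays), viral_pool, derive_seed(seed, "plant"),
            viral_seqs, occupied,
        )
        genomes[pop.name] = g
        if len(frag.arrays):
            truths.append(frag)

    # reference DR FASTA: one record per planted array consensus, labelled
    # with the host population's most specific taxon
    seen_dr = set()
    for frag in truths:
        units = frag.arrays[frag.arrays["kind"] == "unit"]
        for array_id, grp in units.groupby("array_id", sort=True):
            dr = grp["sequence"].iloc[0]
            host = grp["contig"].iloc[0]
            if (host, dr) in seen_dr:
                continue
            seen_dr.add((host, dr))
            path = pop_by_name[host].taxon_path
            taxon = path[-1][1] if path else host
            dr_refs.append(SeqRecord(Seq(dr), id=array_id, description=f"taxon={taxon}"))

    site_truths: list[CommunityTruth] = []
    all_annotations: list[pd.DataFrame] = []
    files: list[Path] = []
    for st in sites:
        active = [p for p in populations if st.population_weights.get(p.name, 0) > 0]
        weights = np.array(
            [st.population_weights[p.name] * p.abundance_weight for p in active]
        )
        weights = weights / weights.sum()
        rng = derive_rng(seed, "site", st.site)
        counts = rng.multinomial(st.n_reads, weights)
        reads, read_rows, contig_recs, contig_rows = [], [], [], []
        for p, nr in zip(active, counts):
            if nr > 0:
                r, t = shred_reads(
                    genomes[p.name], int(nr), st.mean_read_len, st.sd_read_len,
                    derive_seed(seed, "reads", st.site, p.name),
                    id_prefix=f"{st.site}_{p.name}_", site=st.site,
                )
                reads.extend(r)
                read_rows.append(t)
            spans = [
                (int(r.start), int(r.end))
                for frag in truths
                for r in frag.arrays[frag.arrays["contig"] == p.name].itertuples()
            ]
            spans = _merge_spans(spans)
            c, ct = shred_contigs(
                genomes[p.name], st.contig_length_law,
                derive_seed(seed, "contigs", st.site, p.name),
                keep_intact=spans, id_prefix=f"{st.site}_", site=st.site,
            )
            contig_recs.extend(c)
            contig_rows.append(ct)
        site_truth = CommunityTruth(
            reads=pd.concat(read_rows, ignore_index=True) if read_rows else pd.DataFrame(),
            contigs=pd.concat(contig_rows, ignore_index=True) if contig_rows else pd.DataFrame(),
        )
        site_truths.append(site_truth)
        rpath = out / f"{st.site}_reads.fasta"
        cpath = out / f"{st.site}_contigs.fasta"
        _write_fasta(reads, rpath)
        _write_fasta(contig_recs, cpath)
        files.extend([rpath, cpath])
        if family_map and st.category_profile:
            ann = synthesize_annotations(
                contig_recs, st, family_map, derive_seed(seed, "ann", st.site)
            )
            all_annotations.append(ann)

    truth = CommunityTruth.merge(truths + site_truths)
    if all_annotations:
        truth.genes = pd.concat(all_annotations, ignore_index=True)

    vpath = out / "viral.fasta"
    _write_fasta([viral_records[v.id] for v in viral_pool], vpath)
    dpath = out / "reference_dr.fasta"
    _write_fasta(dr_refs, dpath)
    files.extend([vpath, dpath])

    for name in CommunityTruth._FIELDS:
        df = getattr(truth, name)
        tpath = out / f"truth_{name}.tsv"
        (df if len(df) else pd.DataFrame()).to_csv(tpath, sep="\t", index=False)
        files.append(tpath)
    if len(truth.genes):
        apath = out / "annotations.tsv"
        truth.genes.to_csv(apath, sep="\t", index=False)
        files.append(apath)

    manifest = {p.name: _sha256(p) for p in files}
    with open(out / "manifest.tsv", "w") as fh:
        for name in sorted(manifest):
            fh.write(f"{name}\t{manifest[name]}\n")
    return manifest


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge element intervals of one array into a single covering span."""
    if not spans:
        return []
    spans = sorted(spans)
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1] + 200:  # elements of one array are contiguous
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


# ---------------------------------------------------------------------------
# Default study community


def default_community() -> tuple[
    list[SiteSpec], list[PopulationSpec], list[ViralElementSpec],
    list[CrisprArraySpec], dict[str, str],
]:
    """The packaged study community.

    Four archaeal-analogue populations whose G+C targets follow the
    population modes resolved in the source hot springs (38%, 48%, 53.5%,
    62.5%), two sites with contrasting mixtures and functional-category
    profiles, three viral elements, and four CRISPR arrays planting 28
    spacer-virus links: 20 at <=1 mismatch and 8 at 2-3 mismatches.
    """
    populations = [
        PopulationSpec("SulfoT2", 1_000_000, 0.38, 2, 11, 1.0,
                       (("domain", "Archaea"), ("phylum", "Crenarchaeota"),
                        ("order", "Sulfolobales"), ("family", "Sulfolobaceae"),
                        ("genus", "SulfolobusT2"))),
        PopulationSpec("Vulcani", 1_000_000, 0.48, 2, 23, 1.0,
                       (("domain", "Archaea"), ("phylum", "Crenarchaeota"),
                        ("order", "Thermoproteales"), ("family", "Thermoproteaceae"),
                        ("genus", "Vulcanisaeta"))),
        PopulationSpec("SulfoT1", 1_000_000, 0.535, 2, 37, 1.0,
                       (("domain", "Archaea"), ("phylum", "Crenarchaeota"),
                        ("order", "Sulfolobales"), ("family", "Sulfolobaceae"),
                        ("genus", "SulfolobusT1"))),
        PopulationSpec("Acidilo", 1_000_000, 0.625, 2, 53, 1.0,
                       (("domain", "Archaea"), ("phylum", "Crenarchaeota"),
                        ("order", "Desulfurococcales"), ("family", "Acidilobaceae"),
                        ("genus", "Acidilobus"))),
    ]
    viral_pool = [
        ViralElementSpec("vir_A", 30_000, ("siteA", "siteB")),
        ViralElementSpec("vir_B", 20_000, ("siteA",)),
        ViralElementSpec("vir_C", 12_000, ("siteB",)),
    ]
    # 28 links total: 20 at 0-1 mismatches, 8 at 2-3
    arrays = [
        CrisprArraySpec("SulfoT1", dr_length=30, n_units=9, spacer_length=36,
                        links=(("vir_A", 0), ("vir_A", 1), ("vir_A", 0), ("vir_A", 1),
                               ("vir_B", 0), ("vir_B", 1), ("vir_B", 2), ("vir_C", 3))),
        CrisprArraySpec("SulfoT2", dr_length=26, n_units=9, spacer_length=40,
                        links=(("vir_A", 0), ("vir_A", 1), ("vir_B", 0), ("vir_B", 1),
                               ("vir_C", 0), ("vir_C", 1), ("vir_C", 2), ("vir_C", 3))),
        CrisprArraySpec("Vulcani", dr_length=34, n_units=9, spacer_length=33,
                        links=(("vir_A", 0), ("vir_A", 1), ("vir_B", 0), ("vir_B", 1),
                               ("vir_C", 0), ("vir_C", 1), ("vir_A", 2), ("vir_B", 3))),
        CrisprArraySpec("Acidilo", dr_length=29, n_units=7, spacer_length=38,
                        links=(("vir_A", 0), ("vir_C", 1), ("vir_C", 2), ("vir_A", 3)),
                        decoy_fraction=0.3),
    ]
    family_map = {f"FAM{c}{i:02d}": f"cat{c}" for c in "ABCD" for i in range(5)}
    sites = [
        SiteSpec("siteA",
                 {"SulfoT2": 0.4, "Vulcani": 0.1, "SulfoT1": 0.4, "Acidilo": 0.1},
                 {"catA": 0.5, "catB": 0.3, "catC": 0.15, "catD": 0.05},
                 n_reads=2000),
        SiteSpec("siteB",
                 {"SulfoT2": 0.1, "Vulcani": 0.4, "SulfoT1": 0.1, "Acidilo": 0.4},
                 {"catA": 0.1, "catB": 0.2, "catC": 0.3, "catD": 0.4},
                 n_reads=2000),
    ]
    return sites, populations, viral_pool, arrays, family_map


# ---------------------------------------------------------------------------
# Marker-inventory table synthesis


def synthesize_marker_tables(
    design: pd.DataFrame,
    seed: int,
    e_true: float = 1e-30,
    e_reject: float = 1e-20,
) -> dict[str, pd.DataFrame]:
    """Synthetic homology-hit, recheck and bin tables for a planted inventory.

    ``design`` is a bin x marker frame of {"present", "partial", "absent"}.
    For each present/partial cell one true candidate hit is planted; decoy
    candidates that each false-positive elimination rule must reject are
    added on top (wrong-family reciprocal hit, conflicting gene-neighborhood
    function, and a misannotated recheck subject). Returns dict with keys
    ``hits``, ``recheck``, ``neighborhood``, ``bins``, ``queries``, ``truth``.
    """
    rng = derive_rng(seed, "inventory")
    hit_rows, recheck_rows, nbr_rows, bin_rows, truth_rows = [], [], [], [], []
    qlen = 900
    queries = pd.DataFrame(
        [dict(marker_id=m, role="planted", query_length=qlen) for m in design.columns]
    )
    frag_n = 0

    def new_frag(bin_id: str) -> str:
        nonlocal frag_n
        frag_n += 1
        fid = f"frag{frag_n:04d}"
        bin_rows.append(dict(contig_id=fid, bin=bin_id))
        return fid

    for bin_id in design.index:
        for marker in design.columns:
            status = design.loc[bin_id, marker]
            truth_rows.append(dict(bin=bin_id, marker_id=marker, status=status))
            if status == "absent":
                continue
            fid = new_frag(bin_id)
            cov = 0.5 if status == "partial" else 0.9
            alen = int(cov * qlen)
            qstart = int(rng.integers(1, qlen - alen))
            hit_rows.append(_hit_row(fid, marker, alen, qstart, e_true, rng))
            recheck_rows.append(dict(fragment_id=fid, best_family=marker,
                                     misannotated=False))
    markers = list(design.columns)
    bins = list(design.index)
    # decoys, one per elimination rule
    for rule in ("family", "neighborhood", "misannotation"):
        fid = new_frag(bins[int(rng.integers(len(bins)))])
        marker = markers[int(rng.integers(len(markers)))]
        alen = int(0.9 * qlen)
        hit_rows.append(_hit_row(fid, marker, alen, 1, e_reject, rng))
        if rule == "family":
            recheck_rows.append(dict(fragment_id=fid, best_family=f"not_{marker}",
                                     misannotated=False))
        elif rule == "neighborhood":
            recheck_rows.append(dict(fragment_id=fid, best_family=marker,
                                     misannotated=False))
            nbr_rows.append(dict(fragment_id=fid, cluster_function="transposase",
                                 conflicts=True))
        else:
            recheck_rows.append(dict(fragment_id=fid, best_family=marker,
                                     misannotated=True))
        truth_rows.append(dict(bin="", marker_id=marker, status=f"decoy_{rule}"))
    return dict(
        hits=pd.DataFrame(hit_rows),
        recheck=pd.DataFrame(recheck_rows),
        neighborhood=pd.DataFrame(nbr_rows),
        bins=pd.DataFrame(bin_rows),
        queries=queries,
        truth=pd.DataFrame(truth_rows),
    )


def _hit_row(fid: str, marker: str, alen: int, qstart: int, evalue: float,
             rng: np.random.Generator) -> dict:
    """One 12-column tabular alignment row (query = marker gene)."""
    return dict(
        qseqid=marker, sseqid=fid, pident=round(70 + 25 * rng.random(), 2),
        length=alen, mismatch=int(rng.integers(0, 30)), gapopen=0,
        qstart=qstart, qend=qstart + alen - 1, sstart=1, send=alen,
        evalue=evalue, bitscore=round(200 + 300 * rng.random(), 1),
    )
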
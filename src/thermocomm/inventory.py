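"""Curated metabolic-marker inventory across population bins.

Tabular homology hits of marker-gene queries (sqr, sor, dsrAB, hdrABC,
mcrA, amoA, ...) against assembled fragments are screened at a strict
E-value cutoff, then passed through three false-positive elimination
rules — (i) the reciprocal best hit must be the queried family, not merely
a related one; (ii) the fragment's gene neighborhood must not assign the
locus a conflicting function; (iii) the recheck subject must not be a known
misannotation — and surviving hits are rolled up into a population-bin x
marker presence/partial/absence matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "screen_candidates",
    "confirm",
    "build_inventory",
    "format_inventory",
]

CONFIRMED = "confirmed"
PARTIAL = "partial"
REJECTED = "rejected"
NO_EVIDENCE = "no-evidence"


def screen_candidates(
    hit_table: pd.DataFrame,
    queries: pd.DataFrame,
    e_cutoff: float = 1e-10,
) -> pd.DataFrame:
    """Retain marker hits with E-value strictly below the cutoff.

    ``hit_table`` is 12-column tabular alignment output with the marker as
    query; ``queries`` has columns (marker_id, query_length). Query coverage
    is computed from the query coordinates. Malformed rows are skipped and
    counted in a warning.
    """
    needed = ["qseqid", "sseqid", "qstart", "qend", "evalue", "length", "bitscore"]
    df = hit_table.copy()
    for col in ("qstart", "qend", "evalue", "length", "bitscore"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[needed].isna().any(axis=1)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} malformed hit rows skipped")
        df = df[~bad]
    qlen = dict(zip(queries["marker_id"].astype(str), queries["query_length"]))
    df = df[df["qseqid"].astype(str).isin(qlen)]
    df = df[df["evalue"] < e_cutoff]
    out = pd.DataFrame({
        "fragment_id": df["sseqid"].astype(str),
        "marker_id": df["qseqid"].astype(str),
        "evalue": df["evalue"].astype(float),
        "alignment_length": df["length"].astype(int),
        "bitscore": df["bitscore"].astype(float),
    })
    span = (df["qend"] - df["qstart"]).abs() + 1
    out["coverage"] = (span / df["qseqid"].astype(str).map(qlen)).to_numpy()
    return out.reset_index(drop=True)


def confirm(
    candidates: pd.DataFrame,
    recheck: pd.DataFrame,
    neighborhood: pd.DataFrame | None = None,
    coverage_threshold: float = 0.7,
) -> pd.DataFrame:
    """Apply the three false-positive elimination rules to screened hits.

    ``recheck`` maps fragment_id to (best_family, misannotated); rule i fails
    when best_family differs from the candidate's marker, rule ii when the
    optional ``neighborhood`` table flags a conflicting cluster function for
    the fragment (the rule passes vacuously without the table), rule iii when
    the recheck subject is misannotated. Survivors with query coverage below
    ``coverage_threshold`` are ``partial``, the rest ``confirmed``.
    """
    rc = recheck.set_index("fragment_id") if len(recheck) else pd.DataFrame()
    nbr = {}
    if neighborhood is not None and len(neighborhood):
        for row in neighborhood.itertuples(index=False):
            nbr[str(row.fragment_id)] = bool(row.conflicts)
    rows = []
    for cand in candidates.itertuples(index=False):
        fid = str(cand.fragment_id)
        rule_i = rule_ii = rule_iii = False
        if fid not in rc.index:
            status = NO_EVIDENCE
        else:
            entry = rc.loc[fid]
            rule_i = str(entry["best_family"]) != str(cand.marker_id)
            rule_ii = nbr.get(fid, False)
            rule_iii = bool(entry["misannotated"])
            if rule_i or rule_ii or rule_iii:
                status = REJECTED
            elif cand.coverage < coverage_threshold:
                status = PARTIAL
            else:
                status = CONFIRMED
        rows.append(dict(
            fragment_id=fid, marker_id=cand.marker_id, status=status,
            rule_i_family_mismatch=rule_i, rule_ii_neighborhood_conflict=rule_ii,
            rule_iii_misannotation=rule_iii, coverage=cand.coverage,
        ))
    return pd.DataFrame(rows)


def build_inventory(
    confirmed: pd.DataFrame,
    bin_assignment: dict[str, str] | pd.DataFrame,
    markers: list[str] | None = None,
) -> pd.DataFrame:
    """Population-bin x marker presence matrix from confirmed hits.

    Values are ``present`` (>= 1 confirmed hit on a contig of the bin),
    ``partial`` (best surviving status is partial) or ``absent``. Fragments
    without a bin are dropped with a warning. Pass ``markers`` to force
    columns for markers with no hits anywhere (reported all-absent).
    """
    if isinstance(bin_assignment, pd.DataFrame):
        bin_of = dict(zip(bin_assignment["contig_id"].astype(str),
                          bin_assignment["bin"].astype(str)))
    else:
        bin_of = {str(k): str(v) for k, v in bin_assignment.items()}
    surviving = confirmed[confirmed["status"].isin([CONFIRMED, PARTIAL])].copy()
    surviving["bin"] = surviving["fragment_id"].map(bin_of)
    unbinned = surviving["bin"].isna()
    if unbinned.any():
        warnings.warn(f"{int(unbinned.sum())} confirmed fragments not in any bin; dropped")
        surviving = surviving[~unbinned]
    bins = sorted(set(bin_of.values()))
    cols = sorted(set(surviving["marker_id"]) | set(markers or []))
    matrix = pd.DataFrame("absent", index=bins, columns=cols)
    for (bin_id, marker), grp in surviving.groupby(["bin", "marker_id"]):
        matrix.loc[bin_id, marker] = (
            "present" if (grp["status"] == CONFIRMED).any() else "partial"
        )
    matrix.index.name = "bin"
    return matrix


def format_inventory(matrix: pd.DataFrame) -> str:
    """Render the inventory as a text grid (+ present, ~ partial, - absent)."""
    sym = {"present": "+", "partial": "~", "absent": "-"}
    width = max([len(str(b)) for b in matrix.index] + [6])
    header = " " * width + "  " + "  ".join(f"{m:>6}" for m in matrix.columns)
    lines = [header]
    for bin_id, row in matrix.iterrows():
        cells = "  ".join(f"{sym[v]:>6}" for v in row)
        lines.append(f"{str(bin_id):<{width}}  {cells}")
    return "\n".join(lines)
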
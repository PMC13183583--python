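"""Survey of intrinsic disorder around NLS motifs in transcription factors.

For each TF with a predicted nuclear localization signal (NLS), the region
from the NLS to the closest terminus is compared against the full sequence
in terms of mean per-residue disorder (scores in [0, 1], 1 = fully
disordered).  Disorder scores and NLS calls come from external predictors
and are consumed as tabular inputs; this module implements the selection
rules, the region definition, the averaging and the group statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import compare_groups

__all__ = [
    "TFRecord",
    "select_primary_nls",
    "terminal_region",
    "disorder_means",
    "dedup_isoforms",
    "run_survey",
    "read_tf_inputs",
]


@dataclass
class TFRecord:
    """One transcription factor: sequence/length, NLS interval, disorder.

    ``nls`` is (start, end, score), 1-based inclusive residue coordinates.
    ``disorder`` holds one score in [0, 1] per residue.
    """

    id: str
    length: int
    nls: tuple  # (start, end, score)
    disorder: np.ndarray
    sequence: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.disorder = np.asarray(self.disorder, dtype=float)
        if self.length <= 0:
            raise ValueError("length must be positive")
        if len(self.disorder) != self.length:
            raise ValueError("disorder profile must match sequence length")
        if np.any((self.disorder < 0) | (self.disorder > 1)):
            raise ValueError("disorder scores must lie in [0, 1]")
        s, e = int(self.nls[0]), int(self.nls[1])
        if not (1 <= s <= e <= self.length):
            raise ValueError("NLS interval out of bounds")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length mismatch")


def select_primary_nls(candidates):
    """Pick one NLS per TF: highest predictor score, ties to smallest start.

    ``candidates`` is a list of (start, end, score).  An empty list raises,
    signalling that the record is excluded from the survey.
    """
    if not candidates:
        raise ValueError("no NLS candidates; record excluded")
    return max(candidates, key=lambda c: (c[2], -c[0]))


def terminal_region(record: TFRecord):
    """Residue range from the NLS to the closest terminus (NLS included).

    The NLS location is its interval midpoint (start+end)/2; if the
    midpoint falls within the first half of the sequence (inclusive
    boundary) the region runs from residue 1 to the NLS end (side "N"),
    otherwise from the NLS start to the last residue (side "C").
    """
    s, e = int(record.nls[0]), int(record.nls[1])
    midpoint = (s + e) / 2.0
    if midpoint <= record.length / 2.0:
        return "N", (1, e)
    return "C", (s, record.length)


def disorder_means(record: TFRecord):
    """(full-sequence mean, terminal-region mean) of the disorder profile."""
    _, (lo, hi) = terminal_region(record)
    full = float(record.disorder.mean())
    region = float(record.disorder[lo - 1 : hi].mean())
    return full, region


def dedup_isoforms(records, key=None):
    """Keep one record per isoform group: longest sequence, ties by id.

    ``key`` maps a record to its group (default: the part of the id before
    a '-' suffix, the common isoform convention).
    """
    if key is None:
        key = lambda r: r.id.split("-")[0]
    best: dict = {}
    for r in records:
        g = key(r)
        if g not in best:
            best[g] = r
        else:
            cur = best[g]
            if (r.length, ) > (cur.length, ) or (r.length == cur.length and r.id < cur.id):
                best[g] = r
    # preserve input order of the kept records
    kept = set(id(r) for r in best.values())
    return [r for r in records if id(r) in kept]


def run_survey(records):
    """Disorder survey across TF records.

    Returns (rows, stats): a per-record DataFrame with the NLS relative
    position, full and region disorder means, region side and span; and a
    dict with box-plot style summaries, the NLS relative-position
    distribution, and a two-tailed Mann-Whitney comparison of the region
    means against the full-sequence means across records.
    """
    records = [r for r in records if r is not None]
    if len(records) < 2:
        raise ValueError("need at least 2 records with an NLS")
    rows = []
    for r in records:
        side, (lo, hi) = terminal_region(r)
        full, region = disorder_means(r)
        s, e = int(r.nls[0]), int(r.nls[1])
        rows.append(
            {
                "id": r.id,
                "nls_rel_pos": ((s + e) / 2.0) / r.length,
                "full_mean": full,
                "region_mean": region,
                "region_side": side,
                "region_start": lo,
                "region_end": hi,
            }
        )
    table = pd.DataFrame(rows).sort_values("id", kind="stable").reset_index(drop=True)

    def box(x):
        x = np.asarray(x, dtype=float)
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "min": float(x.min()),
            "max": float(x.max()),
        }

    U, p, (mean_r, sem_r), (mean_f, sem_f) = compare_groups(
        table["region_mean"], table["full_mean"]
    )
    statistics = {
        "n": len(table),
        "full": box(table["full_mean"]),
        "region": box(table["region_mean"]),
        "nls_rel_pos": box(table["nls_rel_pos"]),
        "U": U,
        "p_value": p,
        "region_mean": mean_r,
        "region_sem": sem_r,
        "full_mean": mean_f,
        "full_sem": sem_f,
        "nls_in_region": True,  # convention: NLS residues counted in the region
    }
    return table, statistics


def read_tf_inputs(fasta_path=None, disorder_tsv=None, nls_tsv=None):
    """Assemble TFRecords from FASTA + predictor output tables.

    ``disorder_tsv`` columns: id, position (1-based), score.
    ``nls_tsv`` columns: id, start, end, score (1-based inclusive).
    Records without any NLS call are excluded (with reason in the second
    return value).  When a FASTA is given, sequences are attached and used
    for the lengths; otherwise lengths come from the disorder profiles.
    """
    if disorder_tsv is None or nls_tsv is None:
        raise ValueError("disorder and NLS tables are both required")
    seqs = {}
    if fasta_path is not None:
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    dis = pd.read_csv(disorder_tsv, sep="\t")
    nls = pd.read_csv(nls_tsv, sep="\t")
    records, excluded = [], {}
    for tf_id, grp in dis.groupby("id", sort=True):
        grp = grp.sort_values("position")
        scores = grp["score"].to_numpy(dtype=float)
        cands = [
            (int(r.start), int(r.end), float(r.score))
            for r in nls[nls["id"] == tf_id].itertuples()
        ]
        if not cands:
            excluded[tf_id] = "no NLS call"
            continue
        primary = select_primary_nls(cands)
        records.append(
            TFRecord(
                id=str(tf_id),
                length=len(scores),
                nls=primary,
                disorder=scores,
                sequence=seqs.get(tf_id),
            )
        )
    return records, excluded


def write_survey(table, statistics, out_dir):
    """Write the survey table (CSV) and statistics (JSON) to a directory."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "survey.csv", index=False)
    with open(out / "statistics.json", "w") as fh:
        json.dump(statistics, fh, indent=2)
    return out
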
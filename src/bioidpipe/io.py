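"""Readers and writers for the pipeline's plain-text interchange formats.

Everything round-trips through TSV/CSV so intermediate results can be
inspected, diffed, and fed to external tools:

* PSM tables — one row per peptide-spectrum match, semicolon-joined
  protein ids (columns of :data:`bioidpipe.psm.PSM_COLUMNS`).
* Count matrices — a proteins x replicates unique-count TSV plus an
  optional shared-peptide TSV (``peptide_id``, comma-joined ``parents``,
  replicate columns) and a protein metadata TSV (``length``, ``decoy``).
* dNSAF / enrichment / volcano / overlap tables — plain indexed TSVs.
* Tracks — CSV with columns ``track_id, t_seconds, x_nm`` (one row per
  frame), with an optional label sidecar.
* Protein databases — FASTA via Biopython, decoys recognized by id prefix.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .motility import Track
from .psm import DEFAULT_DECOY_PREFIX
from .quant import CountMatrix, empty_shared


def read_psm_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_psm_table(psms: pd.DataFrame, path) -> None:
    psms.to_csv(path, sep="\t", index=False)


def read_fasta_database(path, decoy_prefix: str = DEFAULT_DECOY_PREFIX) -> dict:
    """FASTA -> {protein id: sequence length}; decoy ids keep their prefix."""
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_count_matrix(counts: CountMatrix, prefix) -> None:
    """Write a CountMatrix as ``<prefix>.unique.tsv``, ``<prefix>.shared.tsv``
    and ``<prefix>.proteins.tsv``."""
    prefix = str(prefix)
    counts.unique.rename_axis("protein_id").to_csv(f"{prefix}.unique.tsv", sep="\t")
    shared = counts.shared.copy()
    if len(shared):
        shared["parents"] = [",".join(p) for p in shared["parents"]]
    shared.rename_axis("peptide_id").to_csv(f"{prefix}.shared.tsv", sep="\t")
    meta = pd.DataFrame(
        {"length": counts.lengths, "decoy": counts.decoy}
    ).rename_axis("protein_id")
    meta.to_csv(f"{prefix}.proteins.tsv", sep="\t")


def read_count_matrix(prefix) -> CountMatrix:
    prefix = str(prefix)
    unique = pd.read_csv(f"{prefix}.unique.tsv", sep="\t", index_col="protein_id")
    shared = pd.read_csv(f"{prefix}.shared.tsv", sep="\t", index_col="peptide_id")
    if len(shared):
        shared["parents"] = [tuple(p.split(",")) for p in shared["parents"]]
    else:
        shared = empty_shared(unique.columns)
    meta = pd.read_csv(f"{prefix}.proteins.tsv", sep="\t", index_col="protein_id")
    return CountMatrix(
        unique=unique,
        shared=shared,
        lengths=meta["length"],
        decoy=meta["decoy"].astype(bool),
    )


def write_matrix(df: pd.DataFrame, path, index_name: str = "protein_id") -> None:
    df.rename_axis(index_name).to_csv(path, sep="\t")


def read_matrix(path, index_name: str = "protein_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_name)


def write_tracks(tracks: list[Track], path, labels_path=None) -> None:
    rows = []
    for tr in tracks:
        for t, x in zip(tr.times, tr.positions):
            rows.append({"track_id": tr.track_id, "t_seconds": t, "x_nm": x})
    pd.DataFrame(rows).to_csv(path, index=False)
    if labels_path is not None:
        pd.DataFrame(
            {"track_id": [tr.track_id for tr in tracks],
             "label": [tr.label for tr in tracks]}
        ).to_csv(labels_path, sep="\t", index=False)


def read_tracks(path, labels_path=None) -> list[Track]:
    df = pd.read_csv(path)
    labels = {}
    if labels_path is not None and Path(labels_path).exists():
        lab = pd.read_csv(labels_path, sep="\t")
        labels = dict(zip(lab["track_id"], lab["label"]))
    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        tracks.append(
            Track(
                track_id=str(tid),
                times=grp["t_seconds"].to_numpy(),
                positions=grp["x_nm"].to_numpy(),
                label=labels.get(tid),
            )
        )
    return tracks


def read_coiled_coils(path) -> dict:
    """TSV (protein_id, start, end) -> {protein_id: CoiledCoilAnnotation}."""
    from .screen import CoiledCoilAnnotation

    df = pd.read_csv(path, sep="\t")
    out = {}
    for pid, grp in df.groupby("protein_id"):
        out[pid] = CoiledCoilAnnotation(
            protein_id=pid,
            intervals=list(zip(grp["start"].astype(int), grp["end"].astype(int))),
        )
    return out


def read_hit_lists(path) -> dict:
    """One-column-per-dataset TSV -> {dataset label: frozenset of ids}."""
    df = pd.read_csv(path, sep="\t")
    return {
        col: frozenset(df[col].dropna().astype(str)) for col in df.columns
    }


def write_hit_lists(hit_sets: dict, path) -> None:
    frames = {
        label: pd.Series(sorted(proteins)) for label, proteins in hit_sets.items()
    }
    pd.DataFrame(frames).to_csv(path, sep="\t", index=False)
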
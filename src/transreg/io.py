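"""Readers and writers for abundance tables, transcript sets and motif models.

All tabular formats are tab-delimited text.  Writers prepend ``#`` comment
lines carrying the tool version, a configuration hash and the seed; readers
skip comment lines.  Sequences are FASTA (via Biopython); motif models use
the MEME minimal motif text format.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .errors import SchemaError, ValidationError
from .transcripts import Transcript

LAYERS = ("protein", "total", "free", "monosome", "polysome")
CONDITIONS = ("control", "treated")


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Feature x sample abundance matrix with per-sample metadata.

    Parameters
    ----------
    data : pandas.DataFrame
        Features in rows (unique index), samples in columns.  Values are
        nonnegative reals; NaN marks a missing measurement (e.g. proteomics
        dropout).
    samples : pandas.DataFrame
        Indexed by sample id, with columns ``layer`` (one of
        protein/total/free/monosome/polysome), ``condition``
        (control/treated) and ``unit`` (paired cell-line identifier).
    """

    data: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise SchemaError(f"duplicate feature id {dup!r}")
        if self.samples.index.duplicated().any():
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise SchemaError(f"duplicate sample id {dup!r}")
        missing_meta = set(self.data.columns) - set(self.samples.index)
        if missing_meta:
            raise SchemaError(
                f"samples missing from metadata: {sorted(missing_meta)}"
            )
        for col in ("layer", "condition", "unit"):
            if col not in self.samples.columns:
                raise SchemaError(f"sample metadata lacks column {col!r}")
        bad_layer = set(self.samples["layer"]) - set(LAYERS)
        if bad_layer:
            raise SchemaError(f"unknown layers {sorted(bad_layer)}")
        bad_cond = set(self.samples["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise SchemaError(f"unknown conditions {sorted(bad_cond)}")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("negative abundance value")

    @property
    def features(self) -> pd.Index:
        return self.data.index

    def layers(self) -> list[str]:
        present = self.samples.loc[self.data.columns, "layer"]
        return sorted(set(present), key=LAYERS.index)

    def layer(self, name: str) -> "AbundanceTable":
        """Subset to the samples of one layer."""
        if name not in LAYERS:
            raise SchemaError(f"unknown layer {name!r}")
        cols = [c for c in self.data.columns if self.samples.at[c, "layer"] == name]
        if not cols:
            raise SchemaError(f"no samples for layer {name!r}")
        return AbundanceTable(self.data[cols], self.samples.loc[cols])

    def condition_matrix(self, layer: str, condition: str) -> pd.DataFrame:
        """Columns of one layer x condition, ordered by unit id."""
        meta = self.samples
        cols = [
            c
            for c in self.data.columns
            if meta.at[c, "layer"] == layer and meta.at[c, "condition"] == condition
        ]
        if not cols:
            raise SchemaError(f"no columns for layer={layer!r} condition={condition!r}")
        cols = sorted(cols, key=lambda c: str(meta.at[c, "unit"]))
        return self.data[cols]


def config_hash(config: Mapping | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _header_lines(seed: int | None = None, config: Mapping | None = None) -> list[str]:
    lines = [f"# transreg {__version__}", f"# config_hash {config_hash(config)}"]
    if seed is not None:
        lines.append(f"# seed {seed}")
    return lines


def write_abundance(
    table: AbundanceTable,
    data_path: str | Path,
    metadata_path: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    header = "\n".join(_header_lines(seed, config)) + "\n"
    for path, frame, label in (
        (data_path, table.data, "feature_id"),
        (metadata_path, table.samples.loc[list(table.data.columns)], "sample_id"),
    ):
        with open(path, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, sep="\t", index_label=label, float_format="%.17g")


def read_abundance(data_path: str | Path, metadata_path: str | Path) -> AbundanceTable:
    """Read an abundance matrix plus its sample-metadata sheet."""
    try:
        data = pd.read_csv(data_path, sep="\t", comment="#", index_col=0)
    except ValueError as exc:  # pragma: no cover - pandas-specific messages
        raise ValidationError(f"cannot parse {data_path}: {exc}") from exc
    for j, col in enumerate(data.columns):
        if not pd.api.types.is_numeric_dtype(data[col]):
            bad = data[col][pd.to_numeric(data[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValidationError(
                f"malformed numeric cell at row {row!r}, column {col!r}"
            )
    meta = pd.read_csv(metadata_path, sep="\t", comment="#", index_col=0, dtype=str)
    return AbundanceTable(data.astype(float), meta)


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

def write_transcripts(
    transcripts: Sequence[Transcript],
    fasta_path: str | Path,
    annotation_path: str | Path,
    seed: int | None = None,
) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description="") for t in transcripts
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "transcript_id": t.id,
            "utr5_length": t.utr5_length,
            "cds_length": t.cds_length,
            "utr3_length": t.utr3_length,
        }
        for t in transcripts
    ]
    with open(annotation_path, "w") as fh:
        fh.write("\n".join(_header_lines(seed)) + "\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_transcripts(
    fasta_path: str | Path, annotation_path: str | Path
) -> list[Transcript]:
    """Read FASTA sequences and a region-annotation table into transcripts.

    RNA alphabet input is accepted (U mapped to T); annotated region lengths
    must sum to each sequence length.
    """
    ann = pd.read_csv(annotation_path, sep="\t", comment="#")
    ann = ann.set_index("transcript_id")
    out: list[Transcript] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in ann.index:
            raise ValidationError(f"transcript {rec.id!r} missing from annotation")
        row = ann.loc[rec.id]
        out.append(
            Transcript(
                rec.id,
                str(rec.seq),
                int(row["utr5_length"]),
                int(row["cds_length"]),
                int(row["utr3_length"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def write_meme(
    models: Iterable,
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    """Write motif models (objects with .pwm, .background, .width) in MEME
    minimal motif text format."""
    models = list(models)
    if names is None:
        names = [f"MOTIF_{i + 1}" for i in range(len(models))]
    bg = np.asarray(models[0].background, dtype=float) if models else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {0:.6f} C {1:.6f} G {2:.6f} T {3:.6f}\n\n".format(*bg)
        )
        for name, model in zip(names, models):
            pwm = np.asarray(model.pwm, dtype=float)
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {model.width} "
                f"nsites= 20 E= 0\n"
            )
            for col in pwm.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Read a MEME minimal file; returns (name, pwm[4,W], background[4])."""
    background = np.full(4, 0.25)
    motifs: list[tuple[str, np.ndarray, np.ndarray]] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array([float(parts[k]) for k in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while not lines[i].strip().startswith("letter-probability"):
                i += 1
            width = int(lines[i].split("w=")[1].split()[0])
            rows = []
            for k in range(width):
                rows.append([float(x) for x in lines[i + 1 + k].split()])
            motifs.append((name, np.array(rows).T, background))
            i += 1 + width
            continue
        i += 1
    return motifs


# ---------------------------------------------------------------------------
# run report
# ---------------------------------------------------------------------------

def write_report(
    path: str | Path,
    results=None,
    motif_summary: pd.DataFrame | None = None,
    uorf_summary: pd.DataFrame | None = None,
    config: Mapping | None = None,
    seed: int | None = None,
) -> str:
    """Write a plain-text run report; sections for absent stages are marked.

    Returns the report text.
    """
    if results is None and motif_summary is None and uorf_summary is None:
        raise ValidationError("no stage outputs to report")
    lines = _header_lines(seed, config)
    lines.append("")
    if config:
        lines.append("[config]")
        for key in sorted(config):
            lines.append(f"{key}\t{config[key]}")
        lines.append("")
    if results is not None:
        for layer, frame in (
            ("protein", results.protein_calls),
            ("total", results.rna_calls),
        ):
            lines.append(f"[calls {layer}]")
            for call, n in frame["call"].value_counts().sort_index().items():
                lines.append(f"{call}\t{n}")
            lines.append("")
        lines.append("[shift]")
        for call, n in results.shifts["call"].value_counts().sort_index().items():
            lines.append(f"{call}\t{n}")
        lines.append("")
        lines.append("[groups]")
        sizes = results.group_sizes
        for gid in range(1, 28):
            lines.append(f"group_{gid}\t{int(sizes.get(gid, 0))}")
        lines.append(f"unassigned\t{int(sizes.get('unassigned', 0))}")
        lines.append("")
    else:
        lines.append("[shift]\nabsent\n\n[groups]\nabsent\n")
    for label, frame in (("motif", motif_summary), ("uorf", uorf_summary)):
        lines.append(f"[{label}]")
        if frame is None:
            lines.append("absent")
        else:
            lines.append(frame.to_csv(sep="\t", index=True).rstrip())
        lines.append("")
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text
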
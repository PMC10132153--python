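"""The top-level regulation model: three call layers fitted to one dataset.

``RegulationModel`` wraps a matched multi-layer abundance table;
``fit()`` runs the protein and total-mRNA direction calls, the
polysome/monosome shift test, and the 27-group assignment, returning a
``RegulationResults`` object with the per-feature records, group sizes,
a ``summary()`` table and plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calls import call_layer
from .config import RunConfig
from .errors import SchemaError
from .groups import classify_dataset, correlate_shift_protein, group_triple
from .io import AbundanceTable, read_abundance, write_report
from .shift import shift_layer


class RegulationModel:
    """Classify features into transcriptional vs translational regulation.

    Parameters
    ----------
    table : AbundanceTable
        Combined feature x sample matrix holding (at least) the protein,
        total, monosome and polysome layers with control/treated columns.
    config : RunConfig, optional
        Statistical parameters; defaults follow the conventional analysis
        (alpha 0.05, raw-p gate, 95% CIs with the 70%/130% equivalence
        band, PM-ratio pseudocount 0.5).
    """

    REQUIRED_LAYERS = ("protein", "total", "monosome", "polysome")

    def __init__(self, table: AbundanceTable, config: RunConfig | None = None):
        present = set(table.layers())
        missing = set(self.REQUIRED_LAYERS) - present
        if missing:
            raise SchemaError(f"table lacks required layers: {sorted(missing)}")
        self.table = table
        self.config = config or RunConfig()

    @classmethod
    def from_directory(cls, path: str | Path,
                       config: RunConfig | None = None) -> "RegulationModel":
        """Build from ``abundance.tsv`` + ``samples.tsv`` in a directory."""
        path = Path(path)
        table = read_abundance(path / "abundance.tsv", path / "samples.tsv")
        return cls(table, config)

    def fit(self) -> "RegulationResults":
        cfg = self.config
        kwargs = dict(alpha=cfg.alpha, params=cfg.equivalence, gate=cfg.gate,
                      q=cfg.q, paired=cfg.paired)
        protein_calls = call_layer(self.table, "protein", **kwargs)
        rna_calls = call_layer(self.table, "total", **kwargs)
        shifts = shift_layer(self.table, alpha=cfg.alpha, params=cfg.equivalence,
                             pseudocount=cfg.pseudocount, paired=cfg.paired)
        records, sizes = classify_dataset(protein_calls, rna_calls, shifts)
        return RegulationResults(self, protein_calls, rna_calls, shifts,
                                 records, sizes)


@dataclass
class RegulationResults:
    """Fitted calls, shift records and group assignments."""

    model: RegulationModel
    protein_calls: pd.DataFrame
    rna_calls: pd.DataFrame
    shifts: pd.DataFrame
    records: pd.DataFrame
    group_sizes: pd.Series

    @property
    def n_assigned(self) -> int:
        return int(self.records["group_id"].notna().sum())

    def correlate_shift_protein(self, group_id: int = 4,
                                method: str = "spearman"):
        """(rho, p, n) for log X vs log protein fold change in one group."""
        return correlate_shift_protein(self.records, self.shifts,
                                       self.protein_calls, group_id, method)

    def summary(self) -> str:
        """Plain-text summary in the style of a model-results table."""
        cfg = self.model.config
        lines = [
            "Regulation group classification",
            "=" * 47,
            f"features joined: {len(self.records):>6d}   assigned: "
            f"{self.n_assigned:>6d}",
            f"alpha {cfg.alpha}  gate {cfg.gate}  equivalence "
            f"{cfg.equivalence.lower_factor:.0%}/{cfg.equivalence.upper_factor:.0%}"
            f"  pseudocount {cfg.pseudocount}",
            "-" * 47,
            f"{'group':>5} {'protein':>8} {'rna':>8} {'shift':>8} {'n':>6}",
        ]
        for gid in range(1, 28):
            n = int(self.group_sizes.get(gid, 0))
            if n == 0:
                continue
            p, r, s = group_triple(gid)
            lines.append(f"{gid:>5} {p:>8} {r:>8} {s:>8} {n:>6}")
        lines.append(f"{'none':>5} {'':>8} {'':>8} {'':>8} "
                     f"{int(self.group_sizes.get('unassigned', 0)):>6}")
        lines.append("=" * 47)
        return "\n".join(lines)

    def plot_group_sizes(self, ax=None):
        """Bar chart of assigned-group sizes (matplotlib axis returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        gids = list(range(1, 28))
        ax.bar(gids, [self.group_sizes.get(g, 0) for g in gids], color="#4878d0")
        ax.set_xlabel("regulation group")
        ax.set_ylabel("features")
        ax.set_xticks(gids)
        return ax

    def to_report(self, path, motif_summary=None, uorf_summary=None) -> str:
        return write_report(path, self, motif_summary, uorf_summary,
                            config=self.model.config.to_dict(),
                            seed=self.model.config.seed)
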
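"""Gene-panel definition for the ratio-based TP53 signature.

The assay panel partitions its genes into three roles: genes up-regulated in
TP53-mutant tumours (numerator of the score), genes down-regulated in mutant
tumours (denominator), and internal-control genes used only for QC.  The
published panel has 16 up, 7 down and 3 control genes (26 in total); the gene
identities live in a configuration file, so any panel obeying the same role
structure can be scored without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import PanelError, ParseError

ROLES = ("up", "down", "control")


@dataclass(frozen=True)
class GenePanel:
    """Partition of panel genes by role.

    Parameters
    ----------
    up_genes : list of str
        Genes up-regulated in TP53-mutant tumours; their expression sum is the
        score numerator.  The published panel has 16.
    down_genes : list of str
        Genes down-regulated in mutant tumours; denominator.  Published: 7.
    control_genes : list of str
        Internal controls, used only for detection QC, never in the score.
    """

    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]
    control_genes: tuple[str, ...] = field(default_factory=tuple)

    def __init__(self, up_genes, down_genes, control_genes=()):
        object.__setattr__(self, "up_genes", tuple(up_genes))
        object.__setattr__(self, "down_genes", tuple(down_genes))
        object.__setattr__(self, "control_genes", tuple(control_genes))
        self._validate()

    def _validate(self) -> None:
        if len(self.up_genes) < 1 or len(self.down_genes) < 1:
            raise PanelError("panel needs at least one up and one down gene")
        for name, genes in (("up", self.up_genes), ("down", self.down_genes),
                            ("control", self.control_genes)):
            if len(set(genes)) != len(genes):
                raise PanelError(f"duplicate gene identifiers in {name} list")
        all_genes = self.up_genes + self.down_genes + self.control_genes
        if len(set(all_genes)) != len(all_genes):
            raise PanelError("gene lists must be pairwise disjoint")

    @property
    def scored_genes(self) -> tuple[str, ...]:
        """Genes entering the score (up then down; controls excluded)."""
        return self.up_genes + self.down_genes

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.up_genes + self.down_genes + self.control_genes

    def __len__(self) -> int:
        return len(self.all_genes)


def default_panel() -> GenePanel:
    """Placeholder 16/7/3 panel with generic identifiers.

    The published assay names 26 specific transcripts; since the score depends
    only on the role partition, a generic panel (UP01..UP16, DN01..DN07,
    CTRL1..CTRL3) is shipped for testing and simulation.  Real gene names are
    substituted via a panel file without code change.
    """
    return GenePanel(
        up_genes=[f"UP{i:02d}" for i in range(1, 17)],
        down_genes=[f"DN{i:02d}" for i in range(1, 8)],
        control_genes=[f"CTRL{i}" for i in range(1, 4)],
    )


def load_panel(path: str | Path) -> GenePanel:
    """Read a panel from YAML (role -> gene list) or TSV (gene_id, role)."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ParseError(f"{path}: panel YAML must map roles to gene lists")
        unknown = set(raw) - {"up", "down", "control"}
        if unknown:
            raise ParseError(f"{path}: unknown panel roles {sorted(unknown)}")
        return GenePanel(raw.get("up", []), raw.get("down", []), raw.get("control", []))
    df = pd.read_csv(path, sep=None, engine="python")
    if not {"gene_id", "role"}.issubset(df.columns):
        raise ParseError(f"{path}: panel table needs columns gene_id, role")
    bad = set(df["role"]) - set(ROLES)
    if bad:
        raise ParseError(f"{path}: unknown role value(s) {sorted(bad)}; allowed: {ROLES}")
    by_role = {r: df.loc[df["role"] == r, "gene_id"].tolist() for r in ROLES}
    return GenePanel(by_role["up"], by_role["down"], by_role["control"])


def save_panel(panel: GenePanel, path: str | Path) -> None:
    """Write a panel as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"up": list(panel.up_genes), "down": list(panel.down_genes),
             "control": list(panel.control_genes)},
            fh, sort_keys=False,
        )
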
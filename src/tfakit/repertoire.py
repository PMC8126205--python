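"""The module repertoire: co-expression modules, their genes and activity profiles.

A repertoire catalogues blood co-expression modules.  Each module has a member
gene list and an *activity* vector: for each reference dataset, the signed
percent of member genes changing in that dataset (+ = up-regulated,
- = down-regulated, bounded by ±100).  Member genes additionally carry their
own profile vectors in the same units, used to rank genes within a module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd


@dataclass
class ModuleRepertoire:
    """Module→gene memberships plus module and gene response profiles.

    Parameters
    ----------
    membership : mapping of module id -> list of member gene symbols.
    activity : DataFrame, modules × datasets, signed percent in [-100, 100].
    gene_profiles : DataFrame, genes × datasets, same units.
    """

    membership: dict[str, list[str]]
    activity: pd.DataFrame
    gene_profiles: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if set(self.membership) != set(self.activity.index):
            raise ValueError("membership and activity module ids disagree")
        for module, genes in self.membership.items():
            if not genes:
                raise ValueError(f"module {module} has no member genes")
            missing = [g for g in genes if g not in self.gene_profiles.index]
            if missing:
                raise ValueError(
                    f"module {module} member genes lack profiles: {missing[:5]}"
                )
        if (self.activity.abs() > 100 + 1e-9).any().any():
            raise ValueError("module activity outside [-100, 100]")

    @property
    def module_ids(self) -> list[str]:
        return list(self.activity.index)

    @property
    def n_modules(self) -> int:
        return len(self.activity)

    @property
    def n_datasets(self) -> int:
        return self.activity.shape[1]

    def genes_of(self, module: str) -> list[str]:
        return list(self.membership[module])

    # ----- on-disk layout: a directory of three delimited tables -----

    def write(self, directory: str | Path) -> Path:
        """Write the repertoire as three TSV files under ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = [
            {"module": m, "genes": ";".join(genes)}
            for m, genes in self.membership.items()
        ]
        pd.DataFrame(rows).to_csv(directory / "modules.tsv", sep="\t", index=False)
        self.activity.rename_axis("module").to_csv(
            directory / "activity.tsv", sep="\t"
        )
        self.gene_profiles.rename_axis("gene").to_csv(
            directory / "gene_profiles.tsv", sep="\t"
        )
        return directory

    @classmethod
    def read(cls, directory: str | Path) -> "ModuleRepertoire":
        directory = Path(directory)
        modules = pd.read_csv(directory / "modules.tsv", sep="\t", dtype=str)
        membership = {
            row.module: row.genes.split(";") for row in modules.itertuples()
        }
        activity = pd.read_csv(directory / "activity.tsv", sep="\t", index_col=0)
        profiles = pd.read_csv(
            directory / "gene_profiles.tsv", sep="\t", index_col=0
        )
        return cls(membership=membership, activity=activity, gene_profiles=profiles)
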
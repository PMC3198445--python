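"""Candidate interaction networks (architectures) for the two repression modes.

A transcription–degradation (TD) architecture couples one mRNA gene to the
miRNA(s) degrading it and the proteins acting as its transcriptional
repressors and activators.  A translation–inhibition (TI) architecture
couples a gene and its protein product to 1..max_combo miRNAs blocking
translation.  Families are enumerated combinatorially from a miRNA→target
prediction table (TargetScan/miRanda style) and a per-gene transcription
factor configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, TableParseError

__all__ = [
    "TargetTable",
    "GeneTFSpec",
    "TFConfig",
    "TranscrDegrArch",
    "TranslInhibArch",
    "filter_target_pairs",
    "build_transcr_degr_family",
    "build_transl_inhib_family",
]

_SOURCES = {"TargetScan", "miRanda", "both"}


@dataclass(frozen=True)
class TargetTable:
    """In-silico miRNA→gene target predictions."""

    entries: frozenset[tuple[str, str, str]]  # (mirna_id, gene_id, source)

    def __post_init__(self):
        pairs = [(m, g) for m, g, _ in self.entries]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (mirna, gene) entries in target table")
        bad = {s for _, _, s in self.entries} - _SOURCES
        if bad:
            raise ValueError(f"unknown prediction sources {bad}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], source: str = "both") -> "TargetTable":
        return cls(frozenset((m, g, source) for m, g in pairs))

    @classmethod
    def read(cls, path: str | Path) -> "TargetTable":
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep)
        for col in ("mirna_id", "gene_id", "source"):
            if col not in df.columns:
                raise TableParseError(f"target table missing column {col!r}")
        return cls(frozenset(zip(df.mirna_id.astype(str), df.gene_id.astype(str), df.source.astype(str))))

    def write(self, path: str | Path) -> None:
        sep = "," if str(path).endswith(".csv") else "\t"
        rows = sorted(self.entries, key=lambda e: (e[1], e[0]))
        pd.DataFrame(rows, columns=["mirna_id", "gene_id", "source"]).to_csv(path, sep=sep, index=False)

    def targets(self, mirna: str, gene: str) -> bool:
        return any(m == mirna and g == gene for m, g, _ in self.entries)

    def mirnas_for(self, gene: str) -> list[str]:
        return sorted({m for m, g, _ in self.entries if g == gene})


@dataclass(frozen=True)
class GeneTFSpec:
    """Transcription-factor configuration for one gene."""

    repressors: tuple[str, ...]
    activators: tuple[str, ...]
    mode: str = "fixed"  # "fixed" | "all_nonempty_subsets"

    def __post_init__(self):
        if set(self.repressors) & set(self.activators):
            raise ValueError("repressors and activators must be disjoint")
        if self.mode not in ("fixed", "all_nonempty_subsets"):
            raise ValueError(f"unknown activator combination mode {self.mode!r}")


@dataclass(frozen=True)
class TFConfig:
    genes: dict[str, GeneTFSpec]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TFConfig":
        raw = yaml.safe_load(Path(path).read_text())
        genes = {}
        for gene, spec in raw.items():
            genes[gene] = GeneTFSpec(
                repressors=tuple(spec.get("repressors", [])),
                activators=tuple(spec.get("activators", [])),
                mode=spec.get("mode", "fixed"),
            )
        return cls(genes)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            g: {"repressors": list(s.repressors), "activators": list(s.activators), "mode": s.mode}
            for g, s in self.genes.items()
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


@dataclass(frozen=True)
class TranscrDegrArch:
    """mRNA gene G degraded by miRNA(s), transcription set by rep/act proteins."""

    gene: str
    mirnas: tuple[str, ...]
    rep_proteins: tuple[str, ...]
    act_proteins: tuple[str, ...]

    def __post_init__(self):
        if not self.mirnas:
            raise ValueError("a TD architecture needs at least one miRNA")
        if set(self.rep_proteins) & set(self.act_proteins):
            raise ValueError("repressors and activators must be disjoint")

    @property
    def kind(self) -> str:
        return "Transcr.Degr."

    @property
    def regulator_proteins(self) -> tuple[str, ...]:
        return self.rep_proteins + self.act_proteins

    @property
    def downstream_id(self) -> str:
        return self.gene

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple((m, self.gene) for m in self.mirnas)

    @property
    def arch_id(self) -> str:
        return (
            f"TD:{self.gene}|mir={'+'.join(self.mirnas)}"
            f"|rep={'+'.join(self.rep_proteins)}|act={'+'.join(self.act_proteins)}"
        )


@dataclass(frozen=True)
class TranslInhibArch:
    """Protein P of gene G; translation blocked by 1..3 miRNAs."""

    gene: str
    protein: str
    mirnas: tuple[str, ...]

    def __post_init__(self):
        if not self.mirnas:
            raise ValueError("a TI architecture needs at least one miRNA")

    @property
    def kind(self) -> str:
        return "Transl.Inhib."

    @property
    def downstream_id(self) -> str:
        return self.protein

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple((m, self.gene) for m in self.mirnas)

    @property
    def arch_id(self) -> str:
        return f"TI:{self.gene}|mir={'+'.join(self.mirnas)}"


def arch_from_id(arch_id: str) -> "TranscrDegrArch | TranslInhibArch":
    """Reconstruct an architecture from its canonical id string."""
    kind, rest = arch_id.split(":", 1)
    head, *fields = rest.split("|")
    parts = dict(f.split("=", 1) for f in fields)
    split = lambda s: tuple(x for x in s.split("+") if x)
    if kind == "TD":
        return TranscrDegrArch(
            gene=head,
            mirnas=split(parts.get("mir", "")),
            rep_proteins=split(parts.get("rep", "")),
            act_proteins=split(parts.get("act", "")),
        )
    if kind == "TI":
        return TranslInhibArch(gene=head, protein=head, mirnas=split(parts.get("mir", "")))
    raise ValueError(f"unrecognized architecture id {arch_id!r}")


def filter_target_pairs(
    mirnas: Sequence[str], genes: Sequence[str], table: TargetTable
) -> list[tuple[str, str]]:
    """Cross-product (miRNA, gene) pairs retained when the table predicts them.

    Ordering is deterministic: by gene, then miRNA, lexicographically.
    """
    members = {(m, g) for m, g, _ in table.entries}
    kept = [(m, g) for g in genes for m in mirnas if (m, g) in members]
    return sorted(kept, key=lambda p: (p[1], p[0]))


def build_transcr_degr_family(
    pairs: Sequence[tuple[str, str]], tf_config: TFConfig
) -> list[TranscrDegrArch]:
    """One TD architecture per (pair, activator combination).

    Genes in ``all_nonempty_subsets`` mode contribute one architecture per
    nonempty subset of their activator pool (7 for a 3-protein pool); genes
    in ``fixed`` mode contribute exactly one with the configured lists.
    """
    out: list[TranscrDegrArch] = []
    for mirna, gene in sorted(pairs, key=lambda p: (p[1], p[0])):
        if gene not in tf_config.genes:
            raise ConfigurationError(f"gene {gene!r} missing from TF configuration")
        spec = tf_config.genes[gene]
        if spec.mode == "all_nonempty_subsets":
            pool = sorted(spec.activators)
            for k in range(1, len(pool) + 1):
                for subset in combinations(pool, k):
                    out.append(
                        TranscrDegrArch(
                            gene=gene,
                            mirnas=(mirna,),
                            rep_proteins=tuple(spec.repressors),
                            act_proteins=subset,
                        )
                    )
        else:
            out.append(
                TranscrDegrArch(
                    gene=gene,
                    mirnas=(mirna,),
                    rep_proteins=tuple(spec.repressors),
                    act_proteins=tuple(spec.activators),
                )
            )
    return out


def build_transl_inhib_family(
    gene: str,
    protein: str,
    candidate_mirnas: Sequence[str],
    max_combo: int = 3,
) -> list[TranslInhibArch]:
    """All miRNA subsets of size 1..min(max_combo, n), one architecture each."""
    if max_combo < 1:
        raise ValueError("max_combo must be >= 1")
    candidates = sorted(candidate_mirnas)
    out = []
    for k in range(1, min(max_combo, len(candidates)) + 1):
        for subset in combinations(candidates, k):
            out.append(TranslInhibArch(gene=gene, protein=protein, mirnas=subset))
    return out
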
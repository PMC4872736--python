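"""Shared domain containers and on-disk formats.

Everything downstream of normalization works with a small set of objects:
a log2-scale gene-by-sample :class:`ExpressionMatrix` with an ordinal
:class:`SampleAnnotation`, ranked signed-integer :class:`GeneSignature`
queries, and a :class:`RefSet` of full-universe signed-rank
:class:`ReferenceProfile` instances.  All of them serialize to plain TSV so a
run is inspectable with standard shell tools.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_STAGES: tuple[str, ...] = ("normal", "low", "medium", "high", "AML")


class ConfigurationError(ValueError):
    """A spec/config object violates one of its invariants."""


class MissingGenesError(KeyError):
    """Requested genes are absent from a gene universe or profile."""

    def __init__(self, missing: Iterable[str], context: str = ""):
        self.missing = sorted(missing)
        msg = f"genes missing{' from ' + context if context else ''}: {self.missing}"
        super().__init__(msg)


class FitError(RuntimeError):
    """A model fit could not be performed (too few informative points)."""


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, genes x samples.

    ``values`` is a DataFrame indexed by gene id with one column per sample.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ConfigurationError("ExpressionMatrix: duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ConfigurationError("ExpressionMatrix: duplicate sample ids")
        if self.values.isna().any().any():
            raise ConfigurationError("ExpressionMatrix: missing values not allowed")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(values=df)


@dataclass
class SampleAnnotation:
    """Sample -> ordinal stage mapping plus the stage order itself."""

    groups: pd.Series  # index sample_id, values group label
    group_order: tuple[str, ...] = DEFAULT_STAGES

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        self.group_order = tuple(self.group_order)
        unknown = set(self.groups.unique()) - set(self.group_order)
        if unknown:
            raise ConfigurationError(f"SampleAnnotation: labels not in group_order: {sorted(unknown)}")
        counts = self.groups.value_counts()
        small = [g for g in self.group_order if counts.get(g, 0) < 2]
        if small:
            raise ConfigurationError(f"SampleAnnotation: groups with < 2 samples: {small}")

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"sample_id": self.groups.index, "group": self.groups.values})
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, group_order: Sequence[str] = DEFAULT_STAGES) -> "SampleAnnotation":
        df = pd.read_csv(path, sep="\t", dtype=str)
        s = pd.Series(df["group"].values, index=df["sample_id"].values)
        return cls(groups=s, group_order=tuple(group_order))


@dataclass
class GeneSignature:
    """An ordered signed-rank query signature.

    ``entries`` pairs gene ids with nonzero integer ranks; sign encodes the
    direction of regulation, larger magnitude means more extreme (more
    significant).  The signature builder emits per-direction contiguous ranks
    ({1..n_up} and {-1..-n_down}), but scoring accepts any signed-rank
    multiset, so only the structural requirements are enforced here.
    """

    entries: list[tuple[str, int]]
    signature_id: str = "signature"

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise ConfigurationError(f"GeneSignature {self.signature_id}: duplicate gene ids")
        if any(int(r) == 0 for _, r in self.entries):
            raise ConfigurationError(f"GeneSignature {self.signature_id}: zero rank not allowed")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def ranks(self) -> np.ndarray:
        return np.array([r for _, r in self.entries], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.entries)

    def negated(self) -> "GeneSignature":
        return GeneSignature(
            entries=[(g, -r) for g, r in self.entries],
            signature_id=self.signature_id + "_neg",
        )

    def to_tsv(self, path: str | Path) -> None:
        # headerless two-column format: gene_id TAB signed_rank
        with open(path, "w") as fh:
            for g, r in self.entries:
                fh.write(f"{g}\t{r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, signature_id: str | None = None) -> "GeneSignature":
        path = Path(path)
        entries: list[tuple[str, int]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                g, r = line.split("\t")
                entries.append((g, int(r)))
        return cls(entries=entries, signature_id=signature_id or path.stem)


@dataclass
class ReferenceProfile:
    """One perturbagen instance: a full signed ranking of the gene universe.

    ``signed_ranks`` maps every universe gene to a nonzero integer whose
    magnitudes are a permutation of {1..N}; sign encodes regulation direction.
    """

    instance_id: str
    perturbagen: str
    cell_line: str
    signed_ranks: pd.Series
    dose: str | None = None

    def __post_init__(self) -> None:
        mags = np.sort(np.abs(self.signed_ranks.to_numpy(dtype=np.int64)))
        n = len(mags)
        if not np.array_equal(mags, np.arange(1, n + 1)):
            raise ConfigurationError(
                f"ReferenceProfile {self.instance_id}: |signed_ranks| must be a permutation of 1..N"
            )


@dataclass
class RefSet:
    """A collection of reference profiles over one common gene universe."""

    gene_universe: list[str]
    profiles: list[ReferenceProfile]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p.instance_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("RefSet: instance_ids must be unique")
        universe = set(self.gene_universe)
        for p in self.profiles:
            if set(p.signed_ranks.index) != universe:
                raise ConfigurationError(f"RefSet: profile {p.instance_id} does not cover the universe exactly")

    def __len__(self) -> int:
        return len(self.profiles)

    def rank_matrix(self) -> np.ndarray:
        """Signed ranks as an (n_instances, N) int array, universe order."""
        return np.vstack(
            [p.signed_ranks.reindex(self.gene_universe).to_numpy(dtype=np.int64) for p in self.profiles]
        )

    def to_dir(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        (out_dir / "profiles").mkdir(parents=True, exist_ok=True)
        with open(out_dir / "universe.txt", "w") as fh:
            for g in self.gene_universe:
                fh.write(g + "\n")
        idx = pd.DataFrame(
            {
                "instance_id": [p.instance_id for p in self.profiles],
                "perturbagen": [p.perturbagen for p in self.profiles],
                "cell_line": [p.cell_line for p in self.profiles],
                "dose": [p.dose if p.dose is not None else "" for p in self.profiles],
            }
        )
        idx.to_csv(out_dir / "index.tsv", sep="\t", index=False)
        for p in self.profiles:
            s = p.signed_ranks.reindex(self.gene_universe)
            with open(out_dir / "profiles" / f"{p.instance_id}.tsv", "w") as fh:
                for g, r in s.items():
                    fh.write(f"{g}\t{int(r)}\n")

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "RefSet":
        in_dir = Path(in_dir)
        universe = [line.strip() for line in open(in_dir / "universe.txt") if line.strip()]
        idx = pd.read_csv(in_dir / "index.tsv", sep="\t", dtype=str).fillna("")
        profiles = []
        for _, row in idx.iterrows():
            tab = pd.read_csv(
                in_dir / "profiles" / f"{row['instance_id']}.tsv",
                sep="\t", header=None, names=["gene_id", "signed_rank"],
            )
            s = pd.Series(tab["signed_rank"].to_numpy(dtype=np.int64), index=tab["gene_id"])
            profiles.append(
                ReferenceProfile(
                    instance_id=row["instance_id"],
                    perturbagen=row["perturbagen"],
                    cell_line=row["cell_line"],
                    dose=row["dose"] or None,
                    signed_ranks=s,
                )
            )
        return cls(gene_universe=universe, profiles=profiles, provenance=str(in_dir))


def child_seed(master_seed: int, *keys: int) -> np.random.SeedSequence:
    """Derive a reproducible, order-independent child seed sequence."""
    return np.random.SeedSequence(entropy=int(master_seed) % (2**31), spawn_key=tuple(int(k) for k in keys))
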
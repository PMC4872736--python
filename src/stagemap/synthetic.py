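"""Synthetic inputs with known ground truth.

Three families of generators mirror the three kinds of data the analysis
consumes:

* staged expression cohorts — five ordinal disease stages (healthy marrow,
  low/medium/high progression risk, overt leukemia) with a planted subset of
  genes whose stage means move strictly monotonically, embedded among null
  genes;
* perturbagen reference sets — per-instance latent differential statistics,
  i.i.d. standard Gaussian under the null, with optional planted "inverter"
  (anti-correlated with a query signature) or "mimic" (correlated) instances,
  converted to full signed-rank profiles;
* median-effect dose–response and combination grids — viability wells drawn
  from the median-effect model fa(D) = (D/Dm)^m / (1 + (D/Dm)^m), with a known
  deviation from Loewe additivity for combinations.

Every generator is deterministic for a fixed integer seed and carries its
ground truth alongside the data, so each downstream stage can be tested for
recovery without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import (
    DEFAULT_STAGES,
    ConfigurationError,
    ExpressionMatrix,
    GeneSignature,
    MissingGenesError,
    RefSet,
    SampleAnnotation,
    child_seed,
)
from .connectivity import build_reference_profile

# baseline luminescence of an untreated well, arbitrary instrument units
_BASE_RLU = 10_000.0


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Parameters of a staged expression cohort.

    ``step_effect`` is the per-adjacent-stage shift of a planted gene's mean,
    in log2 units; ``noise_sd`` the within-group Gaussian SD (log2 units).
    """

    n_genes: int = 1000
    group_sizes: tuple[int, ...] = (20, 20, 20, 20, 20)
    n_up_planted: int = 50
    n_down_planted: int = 50
    step_effect: float = 1.0
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    seed: int = 0
    stages: tuple[str, ...] = DEFAULT_STAGES

    def validate(self) -> None:
        if self.n_up_planted + self.n_down_planted > self.n_genes:
            raise ConfigurationError("CohortSpec: n_up_planted + n_down_planted exceeds n_genes")
        if self.step_effect < 0:
            raise ConfigurationError("CohortSpec: step_effect must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("CohortSpec: noise_sd must be >= 0")
        if len(self.group_sizes) != len(self.stages):
            raise ConfigurationError("CohortSpec: group_sizes must match the number of stages")
        if any(n < 2 for n in self.group_sizes):
            raise ConfigurationError("CohortSpec: group_sizes must all be >= 2")


@dataclass
class CohortTruth:
    planted_up: set[str]
    planted_down: set[str]

    def __post_init__(self) -> None:
        if self.planted_up & self.planted_down:
            raise ConfigurationError("CohortTruth: planted_up and planted_down must be disjoint")

    def to_tsv(self, path: str | Path) -> None:
        rows = [(g, "up") for g in sorted(self.planted_up)] + [(g, "down") for g in sorted(self.planted_down)]
        pd.DataFrame(rows, columns=["gene_id", "direction"]).to_csv(path, sep="\t", index=False)


@dataclass
class PlantedConnection:
    """A reference instance built to invert (or mimic) a query signature."""

    instance_index: int
    signature: GeneSignature
    alpha: float = 3.0

    def validate(self, n_instances: int) -> None:
        if not (0 <= self.instance_index < n_instances):
            raise ConfigurationError("PlantedConnection: instance_index out of range")
        if self.alpha < 0:
            raise ConfigurationError("PlantedConnection: alpha must be >= 0")


@dataclass
class RefSetSpec:
    """Parameters of a synthetic perturbagen reference set."""

    n_instances: int = 100
    n_genes_universe: int = 1000
    planted_inverters: list[PlantedConnection] = field(default_factory=list)
    planted_mimics: list[PlantedConnection] = field(default_factory=list)
    noise_sd: float = 1.0
    seed: int = 0
    gene_universe: list[str] | None = None  # explicit universe; else g0000..g{N-1}
    cell_line: str = "HL-60"

    def validate(self) -> None:
        if self.n_instances < 1:
            raise ConfigurationError("RefSetSpec: n_instances must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("RefSetSpec: noise_sd must be >= 0")
        planted = self.planted_inverters + self.planted_mimics
        ids = [p.instance_index for p in planted]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("RefSetSpec: planted instance indices must be distinct")
        for p in planted:
            p.validate(self.n_instances)
        if self.gene_universe is not None and len(self.gene_universe) != self.n_genes_universe:
            raise ConfigurationError("RefSetSpec: gene_universe length must equal n_genes_universe")


@dataclass
class DoseResponseSpec:
    """Median-effect ground truth for one drug.

    ``true_Dm`` (µM) is the median-effect dose (the IC50); ``true_slope`` the
    sigmoidicity m.  ``cv_noise`` is the relative SD of multiplicative
    viability noise per well.
    """

    true_Dm: float = 2.0
    true_slope: float = 1.5
    doses: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
    n_reps: int = 3
    cv_noise: float = 0.05
    seed: int = 0
    drug: str = "drugA"

    def validate(self) -> None:
        if self.true_Dm <= 0:
            raise ConfigurationError("DoseResponseSpec: true_Dm must be > 0")
        if self.true_slope <= 0:
            raise ConfigurationError("DoseResponseSpec: true_slope must be > 0")
        if any(d <= 0 for d in self.doses):
            raise ConfigurationError("DoseResponseSpec: doses must be > 0")
        if self.n_reps < 1:
            raise ConfigurationError("DoseResponseSpec: n_reps must be >= 1")
        if self.cv_noise < 0:
            raise ConfigurationError("DoseResponseSpec: cv_noise must be >= 0")


# ---------------------------------------------------------------------------
# expression cohorts
# ---------------------------------------------------------------------------

def simulate_expression_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, SampleAnnotation, CohortTruth]:
    """Draw a staged cohort with planted strictly monotone genes.

    Planted-up genes gain ``step_effect`` log2 units of mean per adjacent
    stage; planted-down genes lose the same; null genes keep one mean across
    all stages.  Noise is i.i.d. Gaussian on the log2 scale.
    """
    spec.validate()
    rng = np.random.default_rng(child_seed(spec.seed, 0))

    n_stages = len(spec.stages)
    width = max(4, len(str(spec.n_genes - 1)))
    gene_ids = [f"g{i:0{width}d}" for i in range(spec.n_genes)]

    # scatter the planted genes across the universe so gene order carries no signal
    order = rng.permutation(spec.n_genes)
    up_idx = order[: spec.n_up_planted]
    down_idx = order[spec.n_up_planted : spec.n_up_planted + spec.n_down_planted]

    baselines = spec.baseline_mean + rng.normal(0.0, 1.0, size=spec.n_genes)

    stage_shift = np.zeros((spec.n_genes, n_stages))
    steps = np.arange(n_stages, dtype=float)
    stage_shift[up_idx] = spec.step_effect * steps
    stage_shift[down_idx] = -spec.step_effect * steps

    sample_ids: list[str] = []
    groups: list[str] = []
    cols: list[np.ndarray] = []
    for k, (stage, n_k) in enumerate(zip(spec.stages, spec.group_sizes)):
        means_k = baselines + stage_shift[:, k]
        for j in range(n_k):
            sample_ids.append(f"{stage}_{j:03d}")
            groups.append(stage)
            noise = rng.normal(0.0, spec.noise_sd, size=spec.n_genes) if spec.noise_sd > 0 else 0.0
            cols.append(means_k + noise)

    values = pd.DataFrame(np.column_stack(cols), index=gene_ids, columns=sample_ids)
    X = ExpressionMatrix(values=values)
    ann = SampleAnnotation(groups=pd.Series(groups, index=sample_ids), group_order=spec.stages)
    truth = CohortTruth(
        planted_up={gene_ids[i] for i in up_idx},
        planted_down={gene_ids[i] for i in down_idx},
    )
    return X, ann, truth


# ---------------------------------------------------------------------------
# perturbagen reference sets
# ---------------------------------------------------------------------------

def simulate_refset(spec: RefSetSpec) -> tuple[RefSet, pd.DataFrame]:
    """Draw a reference set of signed-rank profiles with planted connections.

    Null instances get i.i.d. standard Gaussian latent differential
    statistics.  An inverter instance gets, over its target signature's
    genes, latent value ``-alpha * sign(query rank)`` plus ``noise_sd``
    Gaussian noise (a mimic gets ``+alpha * sign``), which after signed-rank
    conversion places those genes at the extreme ranks with opposing
    (resp. matching) signs.
    """
    spec.validate()
    rng = np.random.default_rng(child_seed(spec.seed, 1))

    if spec.gene_universe is not None:
        universe = list(spec.gene_universe)
    else:
        width = max(4, len(str(spec.n_genes_universe - 1)))
        universe = [f"g{i:0{width}d}" for i in range(spec.n_genes_universe)]
    gene_pos = {g: i for i, g in enumerate(universe)}

    for planted in spec.planted_inverters + spec.planted_mimics:
        missing = [g for g in planted.signature.genes if g not in gene_pos]
        if missing:
            raise MissingGenesError(missing, context="refset universe")

    latent = rng.standard_normal((spec.n_instances, spec.n_genes_universe))
    truth_rows = []
    for kind, sign in (("inverter", -1.0), ("mimic", +1.0)):
        planted_list = spec.planted_inverters if kind == "inverter" else spec.planted_mimics
        for planted in planted_list:
            idx = np.array([gene_pos[g] for g in planted.signature.genes])
            qsign = np.sign(planted.signature.ranks).astype(float)
            noise = rng.standard_normal(idx.size) * spec.noise_sd
            latent[planted.instance_index, idx] = sign * planted.alpha * qsign + noise
            truth_rows.append(
                {
                    "instance_index": planted.instance_index,
                    "kind": kind,
                    "target_signature": planted.signature.signature_id,
                    "alpha": planted.alpha,
                }
            )

    width_i = max(4, len(str(spec.n_instances - 1)))
    profiles = []
    planted_by_index = {row["instance_index"]: row for row in truth_rows}
    for i in range(spec.n_instances):
        instance_id = f"inst{i:0{width_i}d}"
        row = planted_by_index.get(i)
        perturbagen = f"{row['kind']}_{instance_id}" if row else f"cmpd{i:0{width_i}d}"
        stats = dict(zip(universe, latent[i]))
        profiles.append(
            build_reference_profile(
                stats,
                instance_id=instance_id,
                perturbagen=perturbagen,
                cell_line=spec.cell_line,
                universe=universe,
            )
        )
        if row:
            row["instance_id"] = instance_id
            row["perturbagen"] = perturbagen

    truth = pd.DataFrame(
        truth_rows,
        columns=["instance_index", "instance_id", "perturbagen", "kind", "target_signature", "alpha"],
    )
    refset = RefSet(gene_universe=universe, profiles=profiles, provenance="synthetic")
    return refset, truth


# ---------------------------------------------------------------------------
# dose–response and combination grids
# ---------------------------------------------------------------------------

def fraction_affected(dose: float | np.ndarray, dm: float, slope: float) -> float | np.ndarray:
    """Median-effect fraction affected fa(D) = (D/Dm)^m / (1 + (D/Dm)^m)."""
    ratio = (np.asarray(dose, dtype=float) / dm) ** slope
    return ratio / (1.0 + ratio)


def simulate_dose_response(spec: DoseResponseSpec) -> pd.DataFrame:
    """Viability wells for one drug under the median-effect model.

    Returns a tidy table (``drug``, ``dose``, ``replicate``, ``rlu``) with
    vehicle wells at dose 0 and multiplicative Gaussian noise of relative SD
    ``cv_noise`` on every well.
    """
    spec.validate()
    rng = np.random.default_rng(child_seed(spec.seed, 2))
    rows = []
    for dose in (0.0,) + tuple(spec.doses):
        fa = 0.0 if dose == 0 else fraction_affected(dose, spec.true_Dm, spec.true_slope)
        for rep in range(1, spec.n_reps + 1):
            noise = rng.normal(0.0, spec.cv_noise) if spec.cv_noise > 0 else 0.0
            rlu = _BASE_RLU * (1.0 - fa) * (1.0 + noise)
            rows.append({"drug": spec.drug, "dose": dose, "replicate": rep, "rlu": max(rlu, 0.0)})
    return pd.DataFrame(rows)


def _loewe_fa(d1: float, d2: float, specA: DoseResponseSpec, specB: DoseResponseSpec,
              interaction: float) -> float:
    """Solve for fa such that the summed Loewe dose fractions equal ``interaction``.

    Dx(fa) = Dm * (fa/(1-fa))^(1/m); the left side d1/Dx1 + d2/Dx2 is strictly
    decreasing in fa, so the root is unique.
    """
    def dose_frac(fa: float) -> float:
        odds = fa / (1.0 - fa)
        dx1 = specA.true_Dm * odds ** (1.0 / specA.true_slope)
        dx2 = specB.true_Dm * odds ** (1.0 / specB.true_slope)
        return d1 / dx1 + d2 / dx2

    lo, hi = 1e-12, 1.0 - 1e-12
    f = lambda fa: dose_frac(fa) - interaction
    # dose_frac -> inf as fa -> 0+, -> 0 as fa -> 1-
    return brentq(f, lo, hi, xtol=1e-14, rtol=1e-15)


def simulate_combination_grid(
    specA: DoseResponseSpec,
    specB: DoseResponseSpec,
    interaction: float = 1.0,
    grid: Sequence[float] = (0.0, 0.25, 0.5, 1.0, 2.0),
    seed: int | None = None,
) -> pd.DataFrame:
    """Viability wells for a dose-multiple combination grid of two drugs.

    Grid entries are multiples of each drug's true IC50 (Dm).  Interior wells
    (both doses > 0) realize the effect level at which the summed Loewe dose
    fractions equal ``interaction``: 1 is exactly additive, < 1 synergistic,
    > 1 antagonistic.  Zero-multiple rows/columns reproduce the single-agent
    curves exactly.
    """
    specA.validate()
    specB.validate()
    if interaction <= 0:
        raise ConfigurationError("simulate_combination_grid: interaction must be > 0")
    if any(m < 0 for m in grid):
        raise ConfigurationError("simulate_combination_grid: grid multiples must be >= 0")

    rng = np.random.default_rng(child_seed(seed if seed is not None else specA.seed, 3))
    cv = specA.cv_noise
    n_reps = max(specA.n_reps, specB.n_reps)
    rows = []
    for mA in grid:
        dA = mA * specA.true_Dm
        for mB in grid:
            dB = mB * specB.true_Dm
            if dA == 0 and dB == 0:
                fa = 0.0
            elif dB == 0:
                fa = fraction_affected(dA, specA.true_Dm, specA.true_slope)
            elif dA == 0:
                fa = fraction_affected(dB, specB.true_Dm, specB.true_slope)
            else:
                fa = _loewe_fa(dA, dB, specA, specB, interaction)
            for rep in range(1, n_reps + 1):
                noise = rng.normal(0.0, cv) if cv > 0 else 0.0
                rlu = _BASE_RLU * (1.0 - fa) * (1.0 + noise)
                rows.append(
                    {
                        "drug1": specA.drug, "dose1": dA,
                        "drug2": specB.drug, "dose2": dB,
                        "replicate": rep, "rlu": max(rlu, 0.0),
                    }
                )
    return pd.DataFrame(rows)
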
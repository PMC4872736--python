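"""End-to-end orchestration: simulate -> derive -> connect -> select -> synergy.

One flat TOML config drives the whole run.  Each stage can be toggled; a
disabled stage's outputs are read back from the output directory when a later
stage needs them, so partial re-runs compose.  Every run writes a JSON
manifest recording the configuration, the seeds, and a SHA-256 checksum of
each produced file; re-running the same config reproduces identical
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import connectivity, signature, synergy, synthetic
from .core import ConfigurationError, ExpressionMatrix, GeneSignature, RefSet, SampleAnnotation

logger = logging.getLogger("stagemap.pipeline")

STAGES = ("cohort", "derive", "refset", "connect", "hits", "combo", "synergy")


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run (key = stage.parameter)."""

    out_dir: str = "stagemap_run"
    seed: int = 1
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})

    # cohort
    cohort_n_genes: int = 1000
    cohort_group_sizes: list[int] = field(default_factory=lambda: [20, 20, 20, 20, 20])
    cohort_n_up: int = 50
    cohort_n_down: int = 50
    cohort_step_effect: float = 1.0
    cohort_noise_sd: float = 0.25

    # derive
    derive_q_threshold: float = 0.05
    derive_depths: list[int] = field(default_factory=lambda: [10, 20, 30, 40, 50])

    # refset
    refset_n_instances: int = 100
    refset_inverter_alpha: float = 3.0
    refset_n_mimics: int = 2
    refset_mimic_alpha: float = 3.0

    # connect
    connect_permutations: int = 10_000
    connect_fpr: float = 1.0

    # hits
    hits_min_signatures: int = 2
    hits_direction: str = "negative"

    # combo
    combo_dm_a: float = 2.0
    combo_slope_a: float = 1.5
    combo_dm_b: float = 0.5
    combo_slope_b: float = 2.5
    combo_interaction: float = 0.5
    combo_cv_noise: float = 0.0
    combo_n_reps: int = 3
    combo_grid: list[float] = field(default_factory=lambda: [0.0, 0.25, 0.5, 1.0, 2.0])

    # synergy
    synergy_band: float = 0.1
    synergy_model: str = "exclusive"

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"RunConfig: unknown stages {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, False)

    # -- TOML round trip ----------------------------------------------------

    _SECTIONS = ("run", "stages", "cohort", "derive", "refset", "connect", "hits", "combo", "synergy")

    def to_dict(self) -> dict:
        d: dict[str, dict] = {"run": {"out_dir": self.out_dir, "seed": self.seed},
                              "stages": dict(self.stages)}
        for f in dataclasses.fields(self):
            if f.name in ("out_dir", "seed", "stages"):
                continue
            section, key = f.name.split("_", 1)
            d.setdefault(section, {})[key] = getattr(self, f.name)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs: dict = {}
        run = d.get("run", {})
        kwargs["out_dir"] = run.get("out_dir", "stagemap_run")
        kwargs["seed"] = int(run.get("seed", 1))
        kwargs["stages"] = {s: bool(v) for s, v in d.get("stages", {s: True for s in STAGES}).items()}
        names = {f.name for f in dataclasses.fields(cls)}
        for section, table in d.items():
            if section in ("run", "stages"):
                continue
            for key, value in table.items():
                name = f"{section}_{key}"
                if name not in names:
                    raise ConfigurationError(f"RunConfig: unknown key {section}.{key}")
                kwargs[name] = value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_toml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for section, table in self.to_dict().items():
                fh.write(f"[{section}]\n")
                for key, value in table.items():
                    fh.write(f"{key} = {_toml_value(value)}\n")
                fh.write("\n")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise ConfigurationError(f"cannot serialize config value {v!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


class _Workspace:
    """In-memory hand-off between stages, with on-disk fallback."""

    def __init__(self, out: Path):
        self.out = out
        self.X: ExpressionMatrix | None = None
        self.ann: SampleAnnotation | None = None
        self.signatures: list[GeneSignature] | None = None
        self.refset: RefSet | None = None
        self.results: pd.DataFrame | None = None
        self.combo: pd.DataFrame | None = None

    def need_expression(self) -> tuple[ExpressionMatrix, SampleAnnotation]:
        if self.X is None:
            self.X = ExpressionMatrix.from_tsv(self.out / "expression.tsv")
            self.ann = SampleAnnotation.from_tsv(self.out / "annotation.tsv")
        return self.X, self.ann

    def need_signatures(self) -> list[GeneSignature]:
        if self.signatures is None:
            sig_dir = self.out / "signatures"
            paths = sorted(sig_dir.glob("top*.tsv"), key=lambda p: int(p.stem[3:]))
            self.signatures = [GeneSignature.from_tsv(p) for p in paths]
        if not self.signatures:
            raise ConfigurationError("no signatures available; enable or pre-run the derive stage")
        return self.signatures

    def need_refset(self) -> RefSet:
        if self.refset is None:
            self.refset = RefSet.from_dir(self.out / "refset")
        return self.refset

    def need_results(self) -> pd.DataFrame:
        if self.results is None:
            self.results = pd.read_csv(self.out / "connections.tsv", sep="\t")
        return self.results

    def need_combo(self) -> pd.DataFrame:
        if self.combo is None:
            self.combo = pd.read_csv(self.out / "combo_viability.tsv", sep="\t")
        return self.combo


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest.

    A stage failure raises a RuntimeError naming the stage; outputs written
    up to that point are retained on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ws = _Workspace(out)
    outputs: list[Path] = []

    def record(path: Path) -> None:
        outputs.append(path)

    def run_stage(name, fn):
        if not config.stages.get(name, False):
            logger.info("[%s] disabled; skipping", name)
            return
        logger.info("[%s] running", name)
        try:
            fn()
        except Exception as exc:  # halt with the failing stage named
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    def stage_cohort():
        spec = synthetic.CohortSpec(
            n_genes=config.cohort_n_genes,
            group_sizes=tuple(config.cohort_group_sizes),
            n_up_planted=config.cohort_n_up,
            n_down_planted=config.cohort_n_down,
            step_effect=config.cohort_step_effect,
            noise_sd=config.cohort_noise_sd,
            seed=config.seed,
        )
        X, ann, truth = synthetic.simulate_expression_cohort(spec)
        ws.X, ws.ann = X, ann
        X.to_tsv(out / "expression.tsv"); record(out / "expression.tsv")
        ann.to_tsv(out / "annotation.tsv"); record(out / "annotation.tsv")
        truth.to_tsv(out / "cohort_truth.tsv"); record(out / "cohort_truth.tsv")

    def stage_derive():
        X, ann = ws.need_expression()
        diff = signature.differential_analysis(X, ann)
        diff.to_csv(out / "differential.tsv", sep="\t"); record(out / "differential.tsv")
        inc, dec = signature.monotone_filter(diff, q_threshold=config.derive_q_threshold)
        sigs = signature.build_signatures(inc, dec, depths=config.derive_depths)
        ws.signatures = sigs
        sig_dir = out / "signatures"
        sig_dir.mkdir(exist_ok=True)
        for s in sigs:
            p = sig_dir / f"{s.signature_id}.tsv"
            s.to_tsv(p); record(p)
            meta = {"signature_id": s.signature_id, "n_genes": len(s),
                    "q_threshold": config.derive_q_threshold}
            mp = sig_dir / f"{s.signature_id}.json"
            mp.write_text(json.dumps(meta, indent=2) + "\n"); record(mp)

    def stage_refset():
        X, _ = ws.need_expression()
        sigs = ws.need_signatures()
        target = sigs[-1]  # deepest signature; shallower ones are nested inside it
        n = config.refset_n_instances
        inverters = [synthetic.PlantedConnection(n // 13 + 1, target, config.refset_inverter_alpha)]
        mimics = [
            synthetic.PlantedConnection(n // 7 + 2 + i, target, config.refset_mimic_alpha)
            for i in range(config.refset_n_mimics)
        ]
        spec = synthetic.RefSetSpec(
            n_instances=n,
            n_genes_universe=len(X.gene_ids),
            gene_universe=X.gene_ids,
            planted_inverters=inverters,
            planted_mimics=mimics,
            seed=(config.seed + 1) % (2**31),
        )
        refset, truth = synthetic.simulate_refset(spec)
        ws.refset = refset
        refset.to_dir(out / "refset")
        record(out / "refset" / "index.tsv")
        record(out / "refset" / "universe.txt")
        truth.to_csv(out / "refset_truth.tsv", sep="\t", index=False); record(out / "refset_truth.tsv")

    def stage_connect():
        sigs = ws.need_signatures()
        refset = ws.need_refset()
        policy = connectivity.ThresholdPolicy(config.connect_fpr, len(refset))
        res = connectivity.connect_all(
            sigs, refset, n_permutations=config.connect_permutations,
            seed=(config.seed + 3) % (2**31), policy=policy,
        )
        ws.results = res
        res.to_csv(out / "connections.tsv", sep="\t", index=False); record(out / "connections.tsv")

    def stage_hits():
        res = ws.need_results()
        hits = connectivity.select_hits(
            res, min_signatures=config.hits_min_signatures, direction=config.hits_direction
        )
        hits.to_csv(out / "hits.tsv", sep="\t", index=False); record(out / "hits.tsv")

    def stage_combo():
        specA = synthetic.DoseResponseSpec(
            true_Dm=config.combo_dm_a, true_slope=config.combo_slope_a,
            cv_noise=config.combo_cv_noise, n_reps=config.combo_n_reps,
            seed=(config.seed + 2) % (2**31), drug="drugA",
        )
        specB = synthetic.DoseResponseSpec(
            true_Dm=config.combo_dm_b, true_slope=config.combo_slope_b,
            cv_noise=config.combo_cv_noise, n_reps=config.combo_n_reps,
            seed=(config.seed + 2) % (2**31), drug="drugB",
        )
        grid = synthetic.simulate_combination_grid(
            specA, specB, interaction=config.combo_interaction, grid=config.combo_grid
        )
        ws.combo = grid
        grid.to_csv(out / "combo_viability.tsv", sep="\t", index=False)
        record(out / "combo_viability.tsv")

    def stage_synergy():
        grid = ws.need_combo()
        fitA = synergy.fit_from_table(grid, str(grid["drug1"].iloc[-1]))
        fitB = synergy.fit_from_table(grid, str(grid["drug2"].iloc[-1]))
        ci = synergy.combination_index(
            grid, fitA, fitB, model=config.synergy_model, band=config.synergy_band
        )
        ci.to_csv(out / "combination_index.tsv", sep="\t", index=False)
        record(out / "combination_index.tsv")
        summary = synergy.fit_summary([fitA, fitB])
        summary.to_csv(out / "fit_summary.tsv", sep="\t", index=False)
        record(out / "fit_summary.tsv")

    for name, fn in (
        ("cohort", stage_cohort), ("derive", stage_derive), ("refset", stage_refset),
        ("connect", stage_connect), ("hits", stage_hits), ("combo", stage_combo),
        ("synergy", stage_synergy),
    ):
        run_stage(name, fn)

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
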
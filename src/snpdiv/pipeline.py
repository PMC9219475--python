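"""End-to-end orchestration: simulate/load -> QC -> stats -> tree -> PCA.

`run_full_analysis` writes seven report files plus a JSON manifest into
the output directory; identical config and seed produce byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from snpdiv.distance_nj import asd_matrix, nj_tree, to_newick
from snpdiv.divstats import diversity_table, pairwise_matrices
from snpdiv.genotype_io import GenotypeMatrix, read_ped_map, write_ped_map
from snpdiv.pca import run_pca
from snpdiv.qc import QcThresholds, apply_qc
from snpdiv.simdata import SimulationConfig, simulate_dataset, write_truth

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "qc_report.tsv",
    "diversity.tsv",
    "fst_nm_matrix.tsv",
    "asd_matrix.tsv",
    "tree.nwk",
    "pca_coords.tsv",
    "pca_eigen.tsv",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.__cause__ = cause


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Exactly one of (``ped_path`` & ``map_path``) or ``simulation`` must
    be set.
    """

    out_dir: str | Path
    ped_path: str | Path | None = None
    map_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    thresholds: QcThresholds = field(default_factory=QcThresholds)
    populations: list[str] | None = None
    pca_k: int = 10
    min_overlap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.ped_path is not None and self.map_path is not None
        if has_files == (self.simulation is not None):
            raise ValueError("set exactly one of (ped_path & map_path) or simulation")


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from snpdiv import __version__  # deferred: avoids import cycle

    manifest: dict = {
        "snpdiv_version": __version__,
        "seed": config.seed,
        "config": _echo_config(config),
        "stages": {},
        "outputs": {},
    }

    def stage(name: str):
        logger.info("stage %s starting", name)
        return _StageTimer(name, manifest)

    try:
        with stage("input"):
            if config.simulation is not None:
                gm, truth = simulate_dataset(config.simulation)
                write_ped_map(gm, out / "input.ped", out / "input.map")
                write_truth(truth, out / "truth.tsv")
                manifest["outputs"]["truth"] = str(out / "truth.tsv")
            else:
                gm = read_ped_map(config.ped_path, config.map_path)
            if config.populations:
                gm = gm.subset_populations(config.populations)
            manifest["stages"]["input"].update(
                n_samples=gm.n_samples, n_markers=gm.n_markers
            )

        with stage("qc"):
            gm, report = apply_qc(gm, config.thresholds)
            report.to_tsv(out / "qc_report.tsv")
            manifest["stages"]["qc"].update(
                n_samples_out=report.n_samples_out,
                n_markers_out=report.n_markers_out,
                removed_individuals=len(report.removed_individuals),
                removed_markers={
                    k: len(v) for k, v in report.removed_markers_by_stage.items()
                },
            )

        with stage("diversity"):
            table = diversity_table(gm)
            table.to_tsv(out / "diversity.tsv")
            manifest["stages"]["diversity"].update(n_populations=len(table.populations))

        with stage("fst"):
            pm = pairwise_matrices(gm)
            pm.to_mixed_triangle_tsv(out / "fst_nm_matrix.tsv")
            pm.to_long_dataframe().to_csv(
                out / "fst_nm_long.tsv", sep="\t", index=False, float_format="%.6g"
            )

        with stage("asd"):
            dm = asd_matrix(gm, min_overlap=config.min_overlap)
            dm.to_tsv(out / "asd_matrix.tsv")

        with stage("tree"):
            tree = nj_tree(dm)
            (out / "tree.nwk").write_text(to_newick(tree) + "\n", encoding="utf-8")

        with stage("pca"):
            pca = run_pca(gm, k=config.pca_k)
            pca.coords_dataframe().to_csv(
                out / "pca_coords.tsv", sep="\t", index=False, float_format="%.6g"
            )
            pca.eigen_dataframe().to_csv(
                out / "pca_eigen.tsv", sep="\t", index=False, float_format="%.6g"
            )
    except StageError:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
        raise

    for name in OUTPUT_FILES:
        manifest["outputs"][name.split(".")[0]] = str(out / name)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest


class _StageTimer:
    def __init__(self, name: str, manifest: dict):
        self.name = name
        self.manifest = manifest

    def __enter__(self):
        self.t0 = time.perf_counter()
        self.manifest["stages"][self.name] = {}
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, StageError):
            raise StageError(self.name, self.manifest, exc) from exc
        logger.info(
            "stage %s done in %.2fs", self.name, time.perf_counter() - self.t0
        )
        return False


def _echo_config(config: RunConfig) -> dict:
    echo: dict = {
        "out_dir": str(config.out_dir),
        "pca_k": config.pca_k,
        "min_overlap": config.min_overlap,
        "seed": config.seed,
        "populations": config.populations,
        "thresholds": {
            "snp_call_rate_per_pop": config.thresholds.snp_call_rate_per_pop,
            "indiv_call_rate": config.thresholds.indiv_call_rate,
            "maf_min": config.thresholds.maf_min,
            "hwe_p_min": config.thresholds.hwe_p_min,
        },
    }
    if config.simulation is not None:
        sim = config.simulation
        echo["simulation"] = {
            "n_pops": sim.n_pops,
            "pop_sizes": list(sim.pop_sizes),
            "n_loci": sim.n_loci,
            "bn_F": list(sim.bn_F),
            "fis": list(sim.fis),
            "ancestral_maf_range": list(sim.ancestral_maf_range),
            "missing_rate_snp": sim.missing_rate_snp,
            "missing_rate_indiv": sim.missing_rate_indiv,
            "seed": sim.seed,
        }
    else:
        echo["ped_path"] = str(config.ped_path)
        echo["map_path"] = str(config.map_path)
    return echo


def parse_config_file(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key=value`` config file; '#' starts a comment."""
    values: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, value = line.split("=", 1)
        values[key.strip()] = value.strip()
    return values
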
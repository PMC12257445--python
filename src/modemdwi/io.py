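"""Signal-table I/O, study configuration, and the end-to-end pipeline.

The canonical interchange format is CSV: one row per sample, provenance
columns (sample_id, substrate_id, group_id, level_index, repeat, noise_rep,
label) and one ``b_<value>`` column per b-value.  An optional reader ingests
a 4D NIfTI DWI volume with a plain-text b-value sidecar (one b per volume)
for real acquisitions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import run_study
from .noise import NoiseSpec, add_rician_noise
from .protocol import AcquisitionProtocol
from .simulate import WalkerConfig, generate_dataset
from .substrates import enumerate_substrates

log = logging.getLogger(__name__)

META_COLUMNS = ("sample_id", "substrate_id", "group_id", "level_index",
                "repeat", "noise_rep", "label")


def table_b_values(table: pd.DataFrame) -> np.ndarray:
    """The sorted b grid encoded in a table's b_* column headers."""
    cols = [c for c in table.columns if str(c).startswith("b_")]
    if not cols:
        raise ValueError("no b_* signal columns found")
    try:
        b = np.array([float(str(c)[2:]) for c in cols])
    except ValueError as exc:
        raise ValueError(f"malformed b_* column header: {exc}") from exc
    if np.any(b < 0):
        raise ValueError("negative b-value in header")
    return np.sort(b)


def write_signal_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.17g")


def read_signal_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a signal-table CSV (lossless round trip)."""
    table = pd.read_csv(path)
    b = table_b_values(table)
    cols = [c for c in table.columns if str(c).startswith("b_")]
    sig = table[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(sig)):
        raise ValueError(f"non-finite signal values in {path}")
    log.info("read %d rows x %d b-values from %s", len(table), b.size, path)
    return table


def read_nifti_dwi(nifti_path: str | Path, bval_path: str | Path
                   ) -> pd.DataFrame:
    """Signal table from a 4D NIfTI DWI volume + one-b-per-volume text file.

    Voxels with nonpositive signal in the first (b = 0) volume are dropped.
    Voxel coordinates are retained as x/y/slice columns.
    """
    import nibabel as nib

    img = nib.load(str(nifti_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4D DWI volume, got shape {data.shape}")
    b = np.loadtxt(bval_path, dtype=float).ravel()
    if b.size != data.shape[3]:
        raise ValueError(
            f"b-value count {b.size} != volume count {data.shape[3]}")
    order = np.argsort(b)
    b = b[order]
    data = data[..., order]
    if b[0] != 0:
        raise ValueError("b grid must include b = 0")
    mask = data[..., 0] > 0
    xs, ys, zs = np.nonzero(mask)
    sig = data[mask]
    table = pd.DataFrame(sig, columns=[f"b_{bv:g}" for bv in b])
    table.insert(0, "sample_id", np.arange(len(table)))
    table.insert(1, "x", xs)
    table.insert(2, "y", ys)
    table.insert(3, "slice", zs)
    return table


@dataclass
class StudyConfig:
    """End-to-end pipeline configuration."""

    substrates: str = "cell_size"      # group name or "all"
    profile: str = "ci"                # "ci" | "full"
    noise_levels: tuple[float, ...] = (0.0, 0.05)
    noise_reps: int = 100
    n_sim_repeats: int = 10
    box_cells: int = 64
    methods: tuple[str, ...] = ("modem", "mono", "dki", "froc", "ctrw")
    iterations: int = 10
    master_seed: int = 0
    out_dir: str = "study_out"
    protocol_path: str | None = None

    def __post_init__(self) -> None:
        if any(not 0 <= lv <= 1 for lv in self.noise_levels):
            raise ValueError("noise levels must lie in [0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.protocol_path and not Path(self.protocol_path).exists():
            raise FileNotFoundError(self.protocol_path)

    def protocol(self) -> AcquisitionProtocol:
        if self.protocol_path:
            return AcquisitionProtocol.from_json(self.protocol_path)
        return AcquisitionProtocol()

    def selected_specs(self):
        specs = enumerate_substrates()
        if self.substrates == "all":
            return specs
        sel = [s for s in specs if s.group_id == self.substrates]
        if not sel:
            raise ValueError(f"unknown substrate group: {self.substrates!r}")
        return sel

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        doc = json.loads(Path(path).read_text())
        for key in ("noise_levels", "methods"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(config: StudyConfig) -> dict:
    """simulate -> dope -> evaluate; artifacts + manifest under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocol = config.protocol()
    specs = config.selected_specs()
    walkers = WalkerConfig.from_profile(config.profile,
                                        seed=config.master_seed)
    log.info("simulating %d substrates x %d repeats (%s profile)",
             len(specs), config.n_sim_repeats, config.profile)
    sets = generate_dataset(specs, protocol, walkers,
                            n_sim_repeats=config.n_sim_repeats,
                            box_cells=config.box_cells)

    artifacts: dict[str, str] = {}
    reports: dict[str, dict] = {}
    for level in config.noise_levels:
        noisy = add_rician_noise(sets, NoiseSpec(
            level=level, n_reps=config.noise_reps,
            seed=config.master_seed + 1))
        tag = f"noise{level:g}"
        sig_path = out / f"signals_{tag}.csv"
        write_signal_table(noisy, sig_path)
        artifacts[sig_path.name] = _sha256(sig_path)
        log.info("%s: %d rows", tag, len(noisy))

        report = run_study(noisy, methods=config.methods, protocol=protocol,
                           n_iterations=config.iterations,
                           master_seed=config.master_seed + 2)
        rec_path = out / f"records_{tag}.csv"
        report.records.to_csv(rec_path, index=False)
        artifacts[rec_path.name] = _sha256(rec_path)
        reports[tag] = {
            "summary": {
                m: {"auc_mean": float(g["auc"].mean()),
                    "auc_sd": float(g["auc"].std(ddof=1)),
                    "accuracy_mean": float(g["accuracy"].mean()),
                    "accuracy_sd": float(g["accuracy"].std(ddof=1))}
                for m, g in report.records.groupby("method")},
            "p_values": report.p_values.to_dict(orient="records"),
        }

    report_path = out / "report.json"
    report_path.write_text(json.dumps(reports, indent=2))
    artifacts[report_path.name] = _sha256(report_path)
    manifest = {
        "config": asdict(config),
        "artifacts": artifacts,
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _versions() -> dict[str, str]:
    import numba
    import scipy
    import sklearn
    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "sklearn": sklearn.__version__,
            "numba": numba.__version__}
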
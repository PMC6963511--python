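"""End-to-end orchestration: structures -> descriptors -> assay endpoint ->
prescreen -> subset search -> validation, with a reproducible artifact trail.

One model is fitted per assay concentration (the study design reports one
equation per concentration), each with the activity-stratified train/test
split, an optional single outlier-removal pass, and the full statistics
block. Every run writes a manifest with input hashes, seeds and settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bioassay, qsar, synthetic
from .descriptors import DescriptorMatrix, build_matrix
from .structures import embed_conformer, load_study_compounds, read_structures

__all__ = ["RunConfig", "RunReport", "run"]


@dataclass
class RunConfig:
    structures_path: str | None = None  # None -> packaged 27-compound study set
    assay_path: str | None = None  # None -> simulate from the packaged scenario
    external_descriptors_path: str | None = None
    outdir: str = "terpentox_run"
    endpoint_time: float = 20.0
    concentrations: tuple[float, ...] = (1.0, 10.0, 50.0, 100.0)
    screening: qsar.ScreeningConfig = field(default_factory=qsar.ScreeningConfig)
    max_desc: int = 4
    beam_width: int = 50
    n_test: int = 5
    outlier_z: float = 2.5
    n_conf: int = 20
    seed: int = 42


@dataclass
class RunReport:
    models: dict[float, qsar.FittedModel]
    screens: dict[float, qsar.ScreenReport]
    outdir: Path
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _fit_one_concentration(
    X: DescriptorMatrix,
    y: pd.Series,
    cfg: RunConfig,
) -> tuple[qsar.FittedModel, qsar.ScreenReport, list[str]]:
    audit: list[str] = []
    train_ids, test_ids = qsar.split_train_test(
        list(y.index), y, n_test=cfg.n_test, seed=cfg.seed
    )
    audit.append(f"split: {len(train_ids)} train / {len(test_ids)} test")
    frame = X.values
    X_train, y_train = frame.loc[train_ids], y.loc[train_ids]
    X_test, y_test = frame.loc[test_ids], y.loc[test_ids]

    screen = qsar.prescreen(X_train, y_train, cfg.screening)
    audit.append(
        f"prescreen: {len(screen.surviving)} of {frame.shape[1]} descriptors survive"
    )
    if not screen.surviving:
        raise RuntimeError("prescreen eliminated every descriptor")

    cap = qsar.max_descriptors(len(train_ids), cfg.max_desc)
    sel = qsar.heuristic_search(
        X_train[screen.surviving],
        y_train,
        max_desc=cap,
        beam_width=cfg.beam_width,
        r_pair_max=cfg.screening.r_pair_max,
    )
    audit.extend(sel.audit)
    model = sel.models[0]

    outliers = qsar.flag_outliers(model, X_train, y_train, z_thresh=cfg.outlier_z)
    if outliers:
        audit.append(f"outlier pass: removing {outliers} and refitting once")
        keep = [i for i in train_ids if i not in set(outliers)]
        X_train, y_train = frame.loc[keep], y.loc[keep]
        model = qsar.fit_mlr(X_train[list(model.names)], y_train)
        model.q2 = qsar.loo_q2(X_train[list(model.names)], y_train)
        model.outliers_removed = list(outliers)
    model.r2_test = qsar.evaluate_external(model, X_test, y_test)
    return model, screen, audit


def _table_layout(conc: float, model: qsar.FittedModel) -> str:
    lines = [
        f"Concentration {conc:g} uM "
        f"(N_training = {model.n}, outliers removed: {model.outliers_removed or 'none'})",
        f"{'No':>3} {'B':>12} {'t-test':>10}  descriptor",
        f"{0:>3} {model.intercept:>12.4f} {model.intercept_t:>10.2f}  Intercept",
    ]
    for k, (name, b, t) in enumerate(zip(model.names, model.coefs, model.tstats), start=1):
        lines.append(f"{k:>3} {b:>12.4f} {t:>10.2f}  {name}")
    q2 = "nan" if model.q2 is None else f"{model.q2:.3f}"
    r2t = "nan" if model.r2_test is None else f"{model.r2_test:.3f}"
    lines.append(
        f"    r2_training = {model.r2:.3f}  r2_test = {r2t}  "
        f"F = {model.F:.2f}  s2 = {model.s2:.2f}  Q2 = {q2}"
    )
    return "\n".join(lines)


def run(cfg: RunConfig) -> RunReport:
    """Execute the full pipeline and write all artifacts under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "settings": {
        "endpoint_time": cfg.endpoint_time,
        "concentrations": list(cfg.concentrations),
        "max_desc": cfg.max_desc,
        "beam_width": cfg.beam_width,
        "n_test": cfg.n_test,
        "outlier_z": cfg.outlier_z,
        "n_conf": cfg.n_conf,
        "screening": vars(cfg.screening).copy(),
    }, "inputs": {}}

    # stage: structures
    try:
        if cfg.structures_path is None:
            records = load_study_compounds()
            manifest["inputs"]["structures"] = "packaged study set (27 terpenoids)"
        else:
            records = read_structures(cfg.structures_path)
            manifest["inputs"]["structures"] = {
                "path": cfg.structures_path, "sha256": _sha256(Path(cfg.structures_path))
            }
    except Exception as exc:
        raise RuntimeError(f"[structures] {exc}") from exc

    # stage: descriptors
    try:
        mols = [embed_conformer(r, n_conf=cfg.n_conf, seed=cfg.seed) for r in records]
        X = build_matrix(mols, external=cfg.external_descriptors_path)
        X.to_csv(outdir / "descriptors.csv")
        (outdir / "descriptor_meta.json").write_text(
            json.dumps(X.meta_records(), indent=1) + "\n"
        )
    except Exception as exc:
        raise RuntimeError(f"[descriptors] {exc}") from exc

    # stage: bioassay
    try:
        if cfg.assay_path is None:
            frames = []
            for k, conc in enumerate(cfg.concentrations):
                sim = synthetic.gen_assay_dataset(
                    conc, synthetic.LumSimConfig(seed=cfg.seed + k)
                )
                sim = sim[sim["condition"] != bioassay.CONTROL] if k > 0 else sim
                frames.append(sim)
            series = pd.concat(frames, ignore_index=True)
            manifest["inputs"]["assay"] = "simulated from packaged scenario"
        else:
            series = bioassay.read_luminescence(cfg.assay_path)
            manifest["inputs"]["assay"] = {
                "path": cfg.assay_path, "sha256": _sha256(Path(cfg.assay_path))
            }
        table = bioassay.inhibition_table(series)
        table.to_csv(outdir / "inhibition_table.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"[bioassay] {exc}") from exc

    # stage: modelling, one model per concentration
    models: dict[float, qsar.FittedModel] = {}
    screens: dict[float, qsar.ScreenReport] = {}
    report_blocks: list[str] = []
    for conc in cfg.concentrations:
        try:
            y = bioassay.select_endpoint(table, time=cfg.endpoint_time, concentration=conc)
            y = y.loc[[i for i in X.compound_ids if i in y.index]]
            model, screen, audit = _fit_one_concentration(X, y, cfg)
        except Exception as exc:
            raise RuntimeError(f"[qsar @ {conc:g} uM] {exc}") from exc
        models[conc] = model
        screens[conc] = screen
        (outdir / f"model_{conc:g}uM.json").write_text(
            json.dumps(model.to_dict(), indent=1, sort_keys=True, default=_json_default)
            + "\n"
        )
        (outdir / f"screen_{conc:g}uM.json").write_text(
            json.dumps(
                {"surviving": screen.surviving, "eliminated": screen.rules},
                indent=1, sort_keys=True,
            )
            + "\n"
        )
        (outdir / f"audit_{conc:g}uM.log").write_text("\n".join(audit) + "\n")
        report_blocks.append(_table_layout(conc, model))

    (outdir / "report.txt").write_text("\n\n".join(report_blocks) + "\n")
    manifest["artifacts"] = sorted(p.name for p in outdir.iterdir())
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return RunReport(models=models, screens=screens, outdir=outdir, manifest=manifest)
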
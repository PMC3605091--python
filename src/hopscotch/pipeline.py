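"""End-to-end orchestration: ensemble → clustering → pathway search →
couplings → energetics → rates → report.

Two run modes:

* ``synthetic`` — every input is produced by the generators under a single
  seed: a clustered conformational ensemble is reduced to a working set of
  representative conformations (cluster medoids + reference + late
  snapshots), a planted site model per conformation feeds the pathway
  search and the per-context coupling calculations, planted Gaussian gap
  series feed the reorganization-energy estimator, and Marcus rates close
  the loop.
* ``replay`` — published QM/MD-derived parameters for the CcP/Cytc steps
  are consumed as inputs and only the kinetics layer is recomputed (see
  :mod:`hopscotch.replay`).

Reports are plain dicts (JSON-ready) and byte-reproducible for a fixed
config and seed: no wall-clock timestamps enter the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cluster import kmedoids, select_working_set
from .constants import PhysicalConstants, T_DEFAULT_K
from .coupling import ensemble_coupling_stats, pairwise_couplings, rms_coupling
from .energetics import gap_diagnostics, lambda_linear_response
from .epathway import (
    DEFAULT_CONTACT_CUTOFF,
    DEFAULT_SHARE_THRESHOLD,
    classify_path,
    epathway_search,
    logo_frequencies,
)
from .kinetics import ETStep, compare_mechanisms
from .replay import PATH_DEFINITIONS, replay_report
from .sitemodel import Fragment, SiteModel
from .structures import ETRegion, pairwise_rmsd
from .synthetic import (
    EnsembleSpec,
    GapSpec,
    PlantedSiteSpec,
    gen_ensemble,
    gen_gap_series,
    gen_site_model,
)

logger = logging.getLogger("hopscotch.pipeline")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

#: Planted step energetics defaults: (ΔG° eV, λ eV, acceptor multiplicity).
DEFAULT_STEPS: dict[str, dict] = {
    "DA": {"delta_g": -0.92, "lam": 1.38, "n_a": 2},
    "DB": {"delta_g": -0.55, "lam": 0.88, "n_a": 2},
    "BA": {"delta_g": -0.37, "lam": 0.19, "n_a": 1},
}


@dataclass
class PipelineConfig:
    """Everything a run needs; ``seed`` drives all synthetic randomness."""

    mode: str = "synthetic"  # synthetic | replay
    seed: int = 0
    temperature: float = T_DEFAULT_K
    n_snapshots: int = 2000
    n_clusters: int = 10
    cluster_spread: float = 1.0
    within_cluster_sigma: float = 0.15
    k: int = 10
    n_late_snapshots: int = 3  # nonlocal sampling appended after the window
    contexts: tuple[str, ...] = ("direct", "full", "path1", "path2")
    share_threshold: float = DEFAULT_SHARE_THRESHOLD
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    gap_samples: int = 5
    steps: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_STEPS.items()
    })
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.contexts, list):
            cfg.contexts = tuple(cfg.contexts)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["contexts"] = list(self.contexts)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(cfg: PipelineConfig) -> list[tuple[str, str]]:
    """Return (level, message) findings; never mutates the config."""
    findings: list[tuple[str, str]] = []
    if cfg.mode not in ("synthetic", "replay"):
        findings.append(("error", f"unknown mode {cfg.mode!r}"))
    if cfg.mode == "synthetic" and cfg.seed is None:
        findings.append(("error", "seed is mandatory for synthetic runs"))
    if cfg.k > cfg.n_snapshots:
        findings.append(
            ("error", f"k={cfg.k} exceeds n_snapshots={cfg.n_snapshots}")
        )
    if not 0 < cfg.share_threshold <= 1:
        findings.append(
            ("error", f"share_threshold must be in (0, 1], got {cfg.share_threshold}")
        )
    if cfg.contact_cutoff <= 0:
        findings.append(("error", "contact_cutoff must be positive"))
    elif not 2.0 <= cfg.contact_cutoff <= 10.0:
        findings.append(
            ("warning", f"contact_cutoff {cfg.contact_cutoff} Å outside the "
                        "usual 2–10 Å heavy-atom contact range")
        )
    if cfg.temperature is None:
        findings.append(("warning", f"temperature missing; default {T_DEFAULT_K} K"))
    elif cfg.temperature <= 0:
        findings.append(("error", "temperature must be positive"))
    for label, row in cfg.steps.items():
        if row.get("lam", 1.0) <= 0:
            findings.append(("error", f"step {label}: lambda must be positive"))
        if row.get("n_a", 1) < 1:
            findings.append(("error", f"step {label}: n_a must be >= 1"))
    return findings


def _site_model_for(cfg: PipelineConfig, conformation_seed: int) -> SiteModel:
    return gen_site_model(
        PlantedSiteSpec(seed=int(conformation_seed) % (2**31 - 1))
    )


def _region_from_template(template) -> ETRegion:
    return ETRegion(residues=tuple((c, r) for c, r, _ in template))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the JSON-ready run report.

    Raises ``ValueError`` on config errors.  If ``cfg.output_dir`` is set,
    the report and stage artifacts are persisted there.
    """
    findings = validate_config(cfg)
    errors = [m for lvl, m in findings if lvl == "error"]
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    for lvl, msg in findings:
        getattr(logger, lvl, logger.info)(msg)

    constants = PhysicalConstants(temperature=cfg.temperature)
    report: dict = {
        "provenance": {
            "version": __version__,
            "config": cfg.to_dict(),
            "config_digest": cfg.digest(),
            "seed": cfg.seed,
        }
    }

    if cfg.mode == "replay":
        report["kinetics"] = replay_report(constants)
        _persist(cfg, report)
        return report

    # -- stage 1: conformational sampling + clustering ---------------------
    logger.info("stage 1: ensemble of %d snapshots", cfg.n_snapshots)
    spec = EnsembleSpec(
        n_snapshots=cfg.n_snapshots + cfg.n_late_snapshots,
        n_clusters=cfg.n_clusters,
        cluster_spread=cfg.cluster_spread,
        within_cluster_sigma=cfg.within_cluster_sigma,
        seed=cfg.seed,
    )
    traj = gen_ensemble(spec)
    region = _region_from_template(spec.residue_template)
    dm = pairwise_rmsd(
        traj.__class__(
            chain_ids=traj.chain_ids, res_ids=traj.res_ids,
            res_names=traj.res_names, atom_names=traj.atom_names,
            elements=traj.elements, coords=traj.coords[: cfg.n_snapshots],
        ),
        region,
    )
    cr = kmedoids(dm, cfg.k)
    extras = tuple(range(cfg.n_snapshots, cfg.n_snapshots + cfg.n_late_snapshots))
    working_set = select_working_set(
        cr, extras, reference_index=-1, n_total=traj.n_models
    )
    report["working_set"] = {
        "n_conformations": len(working_set),
        "reference": -1,
        "medoids": list(cr.medoids),
        "late_snapshots": list(extras),
        "clustering_cost_A": cr.cost,
    }

    # -- stage 2: pathway search over the working set ----------------------
    logger.info("stage 2: pathway search on %d conformations", len(working_set))
    results = []
    for i, snap in enumerate(working_set):
        model = _site_model_for(cfg, cfg.seed * 1009 + i)
        pr = epathway_search(
            model,
            contact_cutoff=cfg.contact_cutoff,
            share_threshold=cfg.share_threshold,
        )
        pr.classified_path = classify_path(pr, PATH_DEFINITIONS)
        results.append(pr)
    logo = logo_frequencies(results)
    report["epathway"] = {
        "logo": logo.to_dict(),
        "results": [r.to_dict() for r in results],
        "path_counts": {
            **{
                label: sum(1 for r in results if r.classified_path == label)
                for label in PATH_DEFINITIONS
            },
            "unclassified": sum(1 for r in results if r.classified_path is None),
        },
    }

    # -- stage 3: electronic couplings per context -------------------------
    logger.info("stage 3: couplings over %d contexts", len(cfg.contexts))
    coupling_stats = {}
    for context in cfg.contexts:
        per_snapshot = []
        for i, snap in enumerate(working_set):
            model = _site_model_for(cfg, cfg.seed * 1009 + i)
            cm = pairwise_couplings(model, context, PATH_DEFINITIONS)
            per_snapshot.append(rms_coupling(cm))
        stats = ensemble_coupling_stats(
            np.array(per_snapshot), model.acceptor.degeneracy, context
        )
        coupling_stats[context] = stats.to_dict()
    report["couplings"] = coupling_stats

    # -- stage 4: energetics ----------------------------------------------
    logger.info("stage 4: gap sampling, %d samples per state", cfg.gap_samples)
    energetics = {}
    lam_hat: dict[str, float] = {}
    for j, (label, row) in enumerate(sorted(cfg.steps.items())):
        ro, or_ = gen_gap_series(GapSpec(
            delta_g_true=row["delta_g"],
            lambda_true=row["lam"],
            n_samples=cfg.gap_samples,
            temperature=cfg.temperature,
            seed=(cfg.seed * 31 + j) % (2**31 - 1),
        ))
        lam_hat[label] = lambda_linear_response(ro, or_)
        energetics[label] = {
            "delta_g_eV": row["delta_g"],
            "lambda_planted_eV": row["lam"],
            "lambda_estimate_eV": lam_hat[label],
            "diagnostics_RO": gap_diagnostics(ro, constants),
            "diagnostics_OR": gap_diagnostics(or_, constants),
        }
    report["energetics"] = energetics

    # -- stage 5: kinetics -------------------------------------------------
    logger.info("stage 5: Marcus rates")
    da_v = coupling_stats["full"]["rms_v_eV"]
    steps = {}
    for label, row in cfg.steps.items():
        v = da_v if label == "DA" else _step_coupling(cfg, label, working_set)
        steps[label] = ETStep(
            label=label,
            coupling=v,
            delta_g=row["delta_g"],
            lam=lam_hat[label],
            n_a=row["n_a"],
            constants=constants,
        )
    mech = compare_mechanisms(steps["DA"], (steps["DB"], steps["BA"]))
    report["kinetics"] = {
        "steps": {label: s.to_dict() for label, s in steps.items()},
        "mechanism": mech.to_dict(),
    }

    _persist(cfg, report)
    return report


def _step_coupling(cfg: PipelineConfig, label: str, working_set) -> float:
    """Surrogate coupling of a sub-step on the planted site models.

    DB re-fragments each model with the trap site as a one-state acceptor
    (donor → localized bridge intermediate, full bridge context); BA uses
    the trap as a one-state donor against the original acceptor manifold
    in direct contact.
    """
    per_snapshot = []
    for i, _ in enumerate(working_set):
        base = _site_model_for(cfg, cfg.seed * 1009 + i)
        trap = PlantedSiteSpec().trap_site
        if label == "DB":
            model = SiteModel(
                labels=base.labels, positions=base.positions,
                energies=base.energies, couplings=base.couplings,
                donor=base.donor, acceptor=Fragment(sites=(trap,), degeneracy=1),
            )
            cm = pairwise_couplings(model, "full")
        elif label == "BA":
            model = SiteModel(
                labels=base.labels, positions=base.positions,
                energies=base.energies, couplings=base.couplings,
                donor=Fragment(sites=(trap,), degeneracy=1), acceptor=base.acceptor,
            )
            cm = pairwise_couplings(model, "direct")
        else:
            raise KeyError(label)
        per_snapshot.append(rms_coupling(cm))
    return float(np.sqrt(np.mean(np.array(per_snapshot) ** 2)))


def _persist(cfg: PipelineConfig, report: dict) -> None:
    if not cfg.output_dir:
        return
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("report written to %s", out / "report.json")
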
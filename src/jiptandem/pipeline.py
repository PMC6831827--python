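"""End-to-end orchestration: build -> predict -> compare -> refine -> report.

A run is described by a :class:`RunConfig` (loadable from YAML).  Stages:

1. ``build``    -- assemble the RH1-LZI dimer model from the packaged (or
                   user) sequence and measure its dimensions;
2. ``hydro``    -- bead-model Rg and RPY rigid-body Rh, Svedberg s, f/f0;
3. ``saxs``     -- forward curve; Guinier, dimensionless Kratky, P(r) from
                   the model; if data is present (a measured 3-column file
                   or a synthetic self-curve), chi^2 of model vs data,
                   indirect-transform P(r) and Porod-MoW mass;
4. ``refine``   -- evolutionary rigid-body/linker refinement against data;
5. ``ensemble`` -- pool generation and sub-ensemble Rg-distribution
                   analysis.

Every numeric in the report carries units in its key; the global seed fans
out to fixed per-stage offsets so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import hydrodynamics as hd
from . import model_builder as mb
from . import refinement as rf
from . import scattering as sc
from . import synthetic_data as sd

__all__ = ["RunConfig", "run_pipeline", "validate_config"]

SEED_OFFSETS = {"simulate": 1, "refine": 2, "ensemble": 3}


@dataclass
class RunConfig:
    sequence_fasta: str | None = None     # default: packaged synthetic fixture
    sequence_name: str = "JIP3"
    construct_range: tuple[int, int] = (22, 187)
    nterm_extra: str = "GSH"
    data_path: str | None = None          # measured curve; None -> synthetic
    data_q_unit: str = "A^-1"
    simulate_data: bool = True            # make a synthetic self-curve if no data
    run_guinier: bool = True
    run_kratky: bool = True
    run_pr: bool = True
    run_mass: bool = True
    run_hydro: bool = True
    run_refine: bool = True
    run_ensemble: bool = True
    paper_scale: bool = False             # pool 10000 / 100 cycles instead of scaled-down
    pool_size: int = 1000
    ensemble_cycles: int = 20
    refinement: rf.RefinementSettings = field(default_factory=rf.RefinementSettings)
    mask: rf.FlexibilityMask = field(default_factory=rf.FlexibilityMask)
    output_dir: str = "results/run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        ref = raw.pop("refinement", None)
        msk = raw.pop("mask", None)
        cfg = cls(**raw)
        if ref:
            cfg.refinement = rf.RefinementSettings(**ref)
        if msk:
            msk = {k: tuple(map(tuple, v)) if k in ("rigid", "flexible") else v
                   for k, v in msk.items()}
            cfg.mask = rf.FlexibilityMask(**msk)
        if "construct_range" in raw:
            cfg.construct_range = tuple(raw["construct_range"])
        return cfg


def validate_config(cfg: RunConfig) -> list[str]:
    """Diagnostics for a config; empty list means valid."""
    problems: list[str] = []
    if cfg.sequence_fasta is not None and not Path(cfg.sequence_fasta).exists():
        problems.append(f"sequence file not found: {cfg.sequence_fasta}")
    if cfg.data_path is not None and not Path(cfg.data_path).exists():
        problems.append(f"data file not found: {cfg.data_path}")
    lo, hi = cfg.construct_range
    if lo >= hi:
        problems.append(f"construct range inverted: [{lo}-{hi}]")
    spans = sorted(cfg.mask.rigid + cfg.mask.flexible)
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if a2 <= b1:
            problems.append(f"mask ranges overlap: [{a1}-{b1}] vs [{a2}-{b2}]")
    if cfg.data_path is not None and Path(cfg.data_path).exists():
        try:
            curve = sc.read_curve(cfg.data_path, q_unit=cfg.data_q_unit)
            g = sc.guinier_fit(curve)
            if not 10.0 <= g.Rg <= 1000.0:
                problems.append(
                    f"implausible Guinier Rg {g.Rg:.1f} A from data; check q units "
                    f"(nm^-1 input needs data_q_unit='nm^-1')")
        except ValueError as exc:
            problems.append(f"data file unusable: {exc}")
    return problems


def _build_stage(cfg: RunConfig):
    if cfg.sequence_fasta is None:
        construct = sd.fixture_construct(cfg.sequence_name, cfg.nterm_extra,
                                         *cfg.construct_range)
    else:
        from .sequence_features import SequenceRecord, read_fasta

        rec = read_fasta(cfg.sequence_fasta)[0]
        lo, hi = cfg.construct_range
        construct = SequenceRecord(
            id=rec.id, residues=cfg.nterm_extra + rec.residues[lo - 1:hi],
            first_residue_number=lo - len(cfg.nterm_extra))
    model = mb.assemble_rh1_lzi_dimer(construct)
    return construct, model


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the machine-readable report."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _config_dict(cfg), "seed": cfg.seed, "stages": {}}

    def stage(name, fn):
        try:
            report["stages"][name] = fn()
        except Exception as exc:  # noqa: BLE001 - reported, downstream skipped
            report["stages"][name] = {"error": f"{type(exc).__name__}: {exc}"}
            return False
        return True

    state: dict = {}

    def build():
        construct, model = _build_stage(cfg)
        state["model"] = model
        mb.write_pdb(model, out / "model.pdb")
        return {
            "n_residues_per_chain": int((model.chain == "A").sum()),
            "max_extent_A": mb.max_extent(model),
            "axial_length_A": mb.axial_length(model),
            "lzi_axial_length_A": mb.axial_length(model, sd.JIP3_REGIONS["LZI"]),
            "thickness_A": mb.thickness(model),
            "coordinate_Rg_A": mb.radius_of_gyration(model),
            "chain_symmetry_rmsd_A": mb.chain_symmetry_rmsd(model),
            "pdb": str(out / "model.pdb"),
        }

    if not stage("build", build):
        return _finalize(report, out)
    model = state["model"]

    if cfg.run_hydro:
        def hydro():
            h = hd.predict_hydrodynamics(model)
            return {"Rg_A": h.Rg_A, "Rh_nm": h.Rh_nm, "s_svedberg": h.s_svedberg,
                    "f_ratio": h.f_ratio, "mass_kda": h.mass_kda,
                    "vbar_ml_g": h.vbar_ml_g, "method": h.method}
        stage("hydro", hydro)

    def saxs():
        res: dict = {}
        if cfg.data_path is not None:
            data = sc.read_curve(cfg.data_path, q_unit=cfg.data_q_unit)
            res["data_source"] = cfg.data_path
        elif cfg.simulate_data:
            data = sd.simulate_curve(
                model, noise=sd.NoiseModel(seed=cfg.seed + SEED_OFFSETS["simulate"]))
            sc.write_curve(data, out / "synthetic_data.dat")
            res["data_source"] = "synthetic self-curve"
        else:
            data = None
        model_curve = sd.simulate_curve(model, add_noise=False)
        sc.write_curve(model_curve, out / "model_curve.dat")
        state["data"] = data
        if cfg.run_guinier:
            src = data if data is not None else model_curve
            g = sc.guinier_fit(src)
            state["guinier"] = g
            res["guinier"] = {"Rg_A": g.Rg, "I0": g.I0, "q_range_A^-1":
                              [g.qmin, g.qmax], "qRg_max": g.qRg_max,
                              "r_squared": g.r_squared}
        if cfg.run_kratky and "guinier" in state:
            src = data if data is not None else model_curve
            _, _, peak = sc.dimensionless_kratky(src, state["guinier"].Rg,
                                                 state["guinier"].I0)
            res["kratky_peak"] = {"qRg": peak[0], "height": peak[1]}
        if cfg.run_pr:
            pr = sc.pr_from_structure(model)
            np.savetxt(out / "model_pr.tsv",
                       np.column_stack([pr.r, pr.p]), header="r_A\tP(r)")
            res["model_pr"] = {"Dmax_A": pr.Dmax, "Rg_A": pr.Rg,
                               "mode_r_A": pr.mode_r}
            if data is not None:
                ift = sc.ift_pr(data, Dmax=pr.Dmax * 1.05)
                res["ift_pr"] = {"Dmax_A": ift.Dmax, "Rg_A": ift.Rg,
                                 "mode_r_A": ift.mode_r,
                                 "alpha": ift.metadata.get("alpha"),
                                 "chi2": ift.metadata.get("chi2")}
        if cfg.run_mass and data is not None and "guinier" in state:
            m = sc.porod_mow_mass(data, state["guinier"])
            res["mow_mass"] = {"mass_kda": m.mass_kda,
                               "apparent_volume_A3": m.apparent_volume,
                               "q_m_A^-1": m.q_m}
        if data is not None:
            chi2, scale = sc.chi2_fit(data, model_curve)
            res["chi2_initial"] = chi2
            res["model_scale"] = scale
        return res

    stage("saxs", saxs)
    data = state.get("data")

    if cfg.run_refine and data is not None:
        def refine():
            settings = dataclasses.replace(
                cfg.refinement, seed=cfg.seed + SEED_OFFSETS["refine"])
            r = rf.refine_against_saxs(model, data, cfg.mask, settings)
            mb.write_pdb(r.best, out / "refined.pdb")
            np.savetxt(out / "chi2_trace.tsv", r.trace, header="best_so_far_chi2")
            return {"chi2_initial": r.chi2_initial, "chi2_final": r.chi2_final,
                    "run_chi2": r.run_chi2, "Rg_best_A": r.rg_best,
                    "hinge_bend_deg": r.best_params.hinge_magnitude_deg,
                    "seed": r.seed, "pdb": str(out / "refined.pdb")}
        stage("refine", refine)

    if cfg.run_ensemble and data is not None:
        def ensemble():
            n = 10000 if cfg.paper_scale else cfg.pool_size
            cycles = 100 if cfg.paper_scale else cfg.ensemble_cycles
            rng = np.random.default_rng(cfg.seed + SEED_OFFSETS["ensemble"])
            pool = rf.generate_pool(model, cfg.mask, n=n, rng=rng)
            sel = rf.select_ensemble(pool, data, cycles=cycles,
                                     seed=cfg.seed + SEED_OFFSETS["ensemble"])
            np.savetxt(out / "pool_rg.tsv", pool.rg, header="pool_Rg_A")
            np.savetxt(out / "selected_rg.tsv", sel.rg_selected,
                       header="selected_Rg_A")
            return {"pool_size": len(pool), "mean_rg_pool_A": sel.mean_rg_pool,
                    "mean_rg_selected_A": sel.mean_rg_selected,
                    "chi2_selected": sel.chi2,
                    "run_mean_rgs_A": sel.run_mean_rgs}
        stage("ensemble", ensemble)

    return _finalize(report, out)


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _finalize(report: dict, out: Path) -> dict:
    (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    return str(obj)
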
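"""Rigid-body SAXS refinement with flexible linkers, and ensemble analysis.

The RH1-LZI model has three regions expected to be flexible: the
N-terminal tag + residues 22-25, the hinge between the RH1 bundle and the
coiled coil (residues 67-77), and the C-terminus (177-187).  A conformer
is parameterized by small rigid-body moves at those joints relative to the
starting model:

* a hinge bend -- the whole RH1 block (both chains, residues up to the
  hinge) rotates about a pivot inside the hinge window, with the rotation
  blended across the flexible residues to keep the chain continuous.  This
  is a collective inter-chain domain motion: both chains move as one rigid
  body, so the exact dimer dyad is broken by the bend itself (as it is in
  solution);
* per-chain tail and N-terminal bends applied as mirror images on the two
  chains, which preserve the dyad exactly.

Refinement is an elitist evolutionary search over these parameters scoring
the sigma-weighted chi-square against the data (scale refit at each
evaluation); the ensemble branch generates a pool of hinge conformers and
selects a weighted sub-ensemble whose average curve best fits the data,
comparing the selected Rg distribution with the pool's (the signature of a
preferentially extended or bent solution state).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .model_builder import Structure, radius_of_gyration
from .scattering import ScatteringCurve, chi2_fit, debye_intensity

__all__ = [
    "FlexibilityMask",
    "RefinementSettings",
    "RefinementResult",
    "EnsemblePool",
    "EnsembleSelection",
    "PerturbationError",
    "ConformerParams",
    "apply_conformer",
    "perturb_flexible",
    "hinge_angle",
    "refine_against_saxs",
    "generate_pool",
    "select_ensemble",
]


class PerturbationError(RuntimeError):
    """Raised when no clash-free conformer can be sampled."""


@dataclass(frozen=True)
class FlexibilityMask:
    """Rigid and flexible residue ranges (inclusive, paper numbering)."""

    rigid: tuple[tuple[int, int], ...] = ((26, 66), (78, 176))
    flexible: tuple[tuple[int, int], ...] = ((19, 25), (67, 77), (177, 187))
    hinge_amplitude_deg: float = 20.0
    tail_amplitude_deg: float = 15.0
    nterm_amplitude_deg: float = 15.0

    def __post_init__(self) -> None:
        spans = sorted(self.rigid + self.flexible)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError("rigid and flexible ranges overlap")

    def validate_coverage(self, s: Structure) -> None:
        lo, hi = int(s.resnum.min()), int(s.resnum.max())
        covered = set()
        for a, b in self.rigid + self.flexible:
            covered.update(range(a, b + 1))
        missing = sorted(set(range(lo, hi + 1)) - covered)
        if missing:
            raise ValueError(f"mask does not cover residues {missing[:5]}...")

    @property
    def hinge(self) -> tuple[int, int]:
        """The flexible window separating the two rigid bodies."""
        r = sorted(self.rigid)
        f = sorted(self.flexible)
        for a, b in f:
            if any(b < ra for ra, _ in r) and any(rb < a for _, rb in r):
                return (a, b)
        raise ValueError("mask has no interior flexible window")


@dataclass(frozen=True)
class RefinementSettings:
    population: int = 24
    generations: int = 60
    mutation_deg: float = 10.0
    elite_fraction: float = 0.25
    clash_cutoff: float = 2.5
    seed: int = 0
    n_runs: int = 5

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValueError("population must be >= 4")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass(frozen=True)
class ConformerParams:
    """Joint parameters of one conformer (degrees); zero = starting model."""

    hinge_bend: tuple[float, float] = (0.0, 0.0)    # rotation about x, y at the hinge
    nterm_bend: tuple[float, float] = (0.0, 0.0)
    tail_bend: tuple[float, float] = (0.0, 0.0)

    def as_array(self) -> np.ndarray:
        return np.array([*self.hinge_bend, *self.nterm_bend, *self.tail_bend])

    @staticmethod
    def from_array(v: np.ndarray) -> "ConformerParams":
        return ConformerParams(hinge_bend=(float(v[0]), float(v[1])),
                               nterm_bend=(float(v[2]), float(v[3])),
                               tail_bend=(float(v[4]), float(v[5])))

    @property
    def hinge_magnitude_deg(self) -> float:
        return float(np.hypot(*self.hinge_bend))


@dataclass
class RefinementResult:
    best: Structure
    best_params: ConformerParams
    chi2_initial: float
    chi2_final: float
    trace: np.ndarray                 # per-generation best-so-far chi^2
    rg_best: float
    seed: int
    run_traces: list = field(default_factory=list)
    run_chi2: list = field(default_factory=list)


@dataclass
class EnsemblePool:
    structures: list
    params: list
    rg: np.ndarray

    def __len__(self) -> int:
        return len(self.structures)


@dataclass
class EnsembleSelection:
    indices: np.ndarray
    weights: np.ndarray
    chi2: float
    rg_selected: np.ndarray
    mean_rg_selected: float
    mean_rg_pool: float
    run_mean_rgs: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# conformer geometry
# ---------------------------------------------------------------------------

def _rot_xy(bend_xy: tuple[float, float]) -> np.ndarray:
    """Rotation by a bend vector (degrees about lab x then y)."""
    ax, ay = np.deg2rad(bend_xy[0]), np.deg2rad(bend_xy[1])
    rx = np.array([[1, 0, 0],
                   [0, np.cos(ax), -np.sin(ax)],
                   [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)],
                   [0, 1, 0],
                   [-np.sin(ay), 0, np.cos(ay)]])
    return ry @ rx


def _blended_rotation(xyz: np.ndarray, weights: np.ndarray, rot: np.ndarray,
                      pivot: np.ndarray) -> np.ndarray:
    """Apply ``rot`` about ``pivot`` with per-atom fractional weights.

    Fractional weights interpolate the rotation angle (via matrix fractional
    power approximated by slerp on the axis-angle), keeping the chain
    continuous across a flexible window.
    """
    from scipy.spatial.transform import Rotation, Slerp

    key = Rotation.from_matrix(np.stack([np.eye(3), rot]))
    out = xyz.copy()
    uniq = np.unique(weights)
    for w in uniq:
        if w <= 0:
            continue
        rw = Slerp([0.0, 1.0], key)(w).as_matrix()
        m = weights == w
        out[m] = (xyz[m] - pivot) @ rw.T + pivot
    return out


def apply_conformer(start: Structure, params: ConformerParams,
                    mask: FlexibilityMask | None = None) -> Structure:
    """Deterministically rebuild a conformer from joint parameters.

    The RH1 block (all residues up to and including the hinge window) is
    rotated by the hinge bend about a pivot at the center of the hinge
    window, with the rotation fading from 1 to 0 across the window;
    N-terminal and C-terminal bends rotate the chain ends about their
    anchor residues, mirrored between chains to preserve the dimer dyad.
    """
    mask = mask or FlexibilityMask()
    mask.validate_coverage(start)
    h_lo, h_hi = mask.hinge
    s = start.sorted_by_chain()
    xyz = s.xyz.copy()
    resnum = s.resnum
    chain = s.chain

    # --- hinge bend: collective motion of the lower block (both chains)
    if params.hinge_bend != (0.0, 0.0):
        rot = _rot_xy(params.hinge_bend)
        pivot_mask = resnum == h_hi
        pivot = xyz[pivot_mask].mean(axis=0)
        w = np.zeros(len(s))
        w[resnum < h_lo] = 1.0
        inside = (resnum >= h_lo) & (resnum <= h_hi)
        w[inside] = (h_hi - resnum[inside]) / (h_hi - h_lo)
        xyz = _blended_rotation(xyz, w, rot, pivot)

    # --- mirrored per-chain end moves
    flip = np.diag([-1.0, -1.0, 1.0])
    spans = sorted(mask.flexible)
    nterm_span, cterm_span = spans[0], spans[-1]
    for bend, span, anchor_end in ((params.nterm_bend, nterm_span, "high"),
                                   (params.tail_bend, cterm_span, "low")):
        if bend == (0.0, 0.0):
            continue
        rot_a = _rot_xy(bend)
        rot_b = flip @ rot_a @ flip          # the dyad image of the move
        for ch, rot in (("A", rot_a), ("B", rot_b)):
            m = (chain == ch) & (resnum >= span[0]) & (resnum <= span[1])
            if not m.any():
                continue
            anchor_res = span[1] + 1 if anchor_end == "high" else span[0] - 1
            am = (chain == ch) & (resnum == anchor_res)
            pivot = xyz[am].mean(axis=0) if am.any() else xyz[m].mean(axis=0)
            xyz[m] = (xyz[m] - pivot) @ rot.T + pivot

    out = Structure(chain.copy(), resnum.copy(), s.resname.copy(),
                    s.atomname.copy(), xyz, dict(s.provenance))
    out.provenance["conformer_params"] = params
    return out


def _has_clash(s: Structure, mask: FlexibilityMask, cutoff: float) -> bool:
    """Clash between the two rigid blocks (bonded neighbours excluded)."""
    r = sorted(mask.rigid)
    lower = s.select(resrange=(int(s.resnum.min()), r[0][1]))
    upper = s.select(resrange=(r[-1][0], int(s.resnum.max())))
    if len(lower) == 0 or len(upper) == 0:
        return False
    return bool(cdist(lower.xyz, upper.xyz).min() < cutoff)


def perturb_flexible(s: Structure, mask: FlexibilityMask, rng: np.random.Generator,
                     clash_cutoff: float = 2.5, max_tries: int = 50) -> Structure:
    """One random clash-free conformer around ``s``.

    Bend angles are Gaussian with the mask's per-joint amplitudes; the same
    hinge move acts on both chains (collective domain motion) and end moves
    are mirrored, so the dimer construction stays consistent.
    """
    base = s.provenance.get("conformer_params", ConformerParams())
    base_v = base.as_array() if isinstance(base, ConformerParams) else np.zeros(6)
    start = s.provenance.get("refinement_start", s)
    amps = np.array([mask.hinge_amplitude_deg] * 2
                    + [mask.nterm_amplitude_deg] * 2
                    + [mask.tail_amplitude_deg] * 2)
    for _ in range(max_tries):
        v = base_v + rng.normal(0.0, 1.0, 6) * amps
        cand = apply_conformer(start, ConformerParams.from_array(v), mask)
        if not _has_clash(cand, mask, clash_cutoff):
            cand.provenance["refinement_start"] = start
            return cand
    raise PerturbationError(f"no clash-free conformer in {max_tries} tries")


def hinge_angle(s: Structure, mask: FlexibilityMask | None = None) -> float:
    """Angle (degrees) between the RH1-block axis and the coil axis."""
    mask = mask or FlexibilityMask()
    r = sorted(mask.rigid)
    low = s.select(resrange=r[0])
    high = s.select(resrange=r[-1])

    def axis(sub: Structure) -> np.ndarray:
        x = sub.xyz - sub.xyz.mean(axis=0)
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        v = vt[0]
        return v if v[2] >= 0 else -v

    cosang = np.clip(abs(float(axis(low) @ axis(high))), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# evolutionary refinement
# ---------------------------------------------------------------------------

def _chi2_of(s: Structure, data: ScatteringCurve) -> float:
    model = debye_intensity(s, data.q, method="histogram")
    return chi2_fit(data, model)[0]


def _single_run(start: Structure, data: ScatteringCurve, mask: FlexibilityMask,
                settings: RefinementSettings, seed: int):
    rng = np.random.default_rng(seed)
    amps = np.array([mask.hinge_amplitude_deg] * 2
                    + [mask.nterm_amplitude_deg] * 2
                    + [mask.tail_amplitude_deg] * 2)

    def evaluate(v: np.ndarray) -> float:
        cand = apply_conformer(start, ConformerParams.from_array(v), mask)
        if _has_clash(cand, mask, settings.clash_cutoff):
            return np.inf
        return _chi2_of(cand, data)

    pop = [np.zeros(6)]
    while len(pop) < settings.population:
        pop.append(rng.normal(0.0, 1.0, 6) * amps)
    scores = np.array([evaluate(v) for v in pop])
    n_elite = max(1, int(settings.elite_fraction * settings.population))
    trace = []
    for _ in range(settings.generations):
        order = np.argsort(scores, kind="stable")
        pop = [pop[i] for i in order]
        scores = scores[order]
        trace.append(scores[0])
        children, child_scores = [], []
        while len(children) < settings.population - n_elite:
            parent = pop[rng.integers(0, n_elite)]
            child = parent + rng.normal(0.0, settings.mutation_deg, 6)
            children.append(child)
            child_scores.append(evaluate(child))
        pop = pop[:n_elite] + children
        scores = np.concatenate([scores[:n_elite], np.array(child_scores)])
    order = np.argsort(scores, kind="stable")
    best_v, best_chi2 = pop[order[0]], float(scores[order[0]])
    trace.append(best_chi2)
    return best_v, best_chi2, np.minimum.accumulate(np.array(trace))


def refine_against_saxs(start: Structure, data: ScatteringCurve,
                        mask: FlexibilityMask | None = None,
                        settings: RefinementSettings | None = None) -> RefinementResult:
    """Elitist evolutionary rigid-body/flexible-linker refinement.

    ``settings.n_runs`` independent runs are executed with derived seeds;
    the best run is reported along with every run's final chi^2.  Ties on
    chi^2 break toward the smaller Rg deviation from the start, then run
    order.
    """
    if data.sigma is None:
        raise ValueError("refinement needs data uncertainties")
    mask = mask or FlexibilityMask()
    settings = settings or RefinementSettings()
    chi2_init = _chi2_of(start, data)
    rg_start = radius_of_gyration(start)
    runs = []
    for k in range(settings.n_runs):
        v, chi2, trace = _single_run(start, data, mask, settings,
                                     seed=settings.seed + 1000 * k)
        best = apply_conformer(start, ConformerParams.from_array(v), mask)
        runs.append((chi2, abs(radius_of_gyration(best) - rg_start), k, v, trace, best))
    runs.sort(key=lambda t: (round(t[0], 12), t[1], t[2]))
    chi2_best, _, k_best, v_best, trace_best, best = runs[0]
    chi2_final = min(chi2_best, chi2_init)
    return RefinementResult(
        best=best if chi2_best <= chi2_init else start,
        best_params=ConformerParams.from_array(v_best),
        chi2_initial=chi2_init,
        chi2_final=chi2_final,
        trace=np.minimum(trace_best, chi2_init),
        rg_best=radius_of_gyration(best if chi2_best <= chi2_init else start),
        seed=settings.seed + 1000 * k_best,
        run_traces=[t[4] for t in runs],
        run_chi2=[float(t[0]) for t in runs],
    )


# ---------------------------------------------------------------------------
# pool generation + ensemble selection
# ---------------------------------------------------------------------------

def generate_pool(start: Structure, mask: FlexibilityMask | None = None,
                  n: int = 1000, rng: np.random.Generator | None = None,
                  clash_cutoff: float = 2.5) -> EnsemblePool:
    """Pool of clash-free hinge conformers (linker-only flexibility).

    Only the interior flexible window moves: end amplitudes are zeroed, so
    pool diversity reflects the hinge bend alone, as in the ensemble
    analysis of the solution state.
    """
    if n < 10:
        raise ValueError("pool size must be >= 10")
    mask = mask or FlexibilityMask()
    linker_mask = replace(mask, nterm_amplitude_deg=0.0, tail_amplitude_deg=0.0)
    rng = rng or np.random.default_rng(0)
    structures, params, rgs = [], [], []
    for _ in range(n):
        if linker_mask.hinge_amplitude_deg == 0.0:
            cand = apply_conformer(start, ConformerParams(), mask)
        else:
            cand = perturb_flexible(start, linker_mask, rng, clash_cutoff)
        p = cand.provenance.get("conformer_params", ConformerParams())
        structures.append(cand)
        params.append(p)
        rgs.append(radius_of_gyration(cand))
    return EnsemblePool(structures=structures, params=params, rg=np.array(rgs))


def select_ensemble(pool: EnsemblePool, data: ScatteringCurve,
                    ensemble_size: int = 20, cycles: int = 20,
                    population: int = 30, n_runs: int = 5,
                    seed: int = 0) -> EnsembleSelection:
    """Genetic selection of a weighted sub-ensemble fitting the data.

    Chromosomes are multisets of ``ensemble_size`` pool indices (repetition
    allowed; multiplicity acts as weight).  Fitness is the chi^2 of the
    multiset-averaged curve with the scale refit.  The runs' selected Rg
    distributions are pooled into the reported selection.
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    if data.sigma is None:
        raise ValueError("ensemble selection needs data uncertainties")
    curves = np.stack([
        debye_intensity(s, data.q, method="histogram").I for s in pool.structures])
    s2 = data.sigma ** 2

    def chi2_of_multiset(idx: np.ndarray) -> float:
        im = curves[idx].mean(axis=0)
        scale = (data.I * im / s2).sum() / (im ** 2 / s2).sum()
        return float((((data.I - scale * im) / data.sigma) ** 2).sum()
                     / max(len(data) - 1, 1))

    best_overall = None
    run_mean_rgs = []
    all_selected = []
    for run in range(n_runs):
        rng = np.random.default_rng(seed + 7919 * run)
        popu = [rng.integers(0, len(pool), ensemble_size) for _ in range(population)]
        scores = np.array([chi2_of_multiset(i) for i in popu])
        n_elite = max(1, population // 4)
        for _ in range(cycles):
            order = np.argsort(scores, kind="stable")
            popu = [popu[i] for i in order]
            scores = scores[order]
            children, child_scores = [], []
            while len(children) < population - n_elite:
                p1 = popu[rng.integers(0, n_elite)]
                p2 = popu[rng.integers(0, n_elite)]
                cross = rng.random(ensemble_size) < 0.5
                child = np.where(cross, p1, p2).copy()
                n_mut = rng.integers(1, max(2, ensemble_size // 5))
                pos = rng.integers(0, ensemble_size, n_mut)
                child[pos] = rng.integers(0, len(pool), n_mut)
                children.append(child)
                child_scores.append(chi2_of_multiset(child))
            popu = popu[:n_elite] + children
            scores = np.concatenate([scores[:n_elite], np.array(child_scores)])
        order = np.argsort(scores, kind="stable")
        sel, chi = popu[order[0]], float(scores[order[0]])
        run_mean_rgs.append(float(pool.rg[sel].mean()))
        all_selected.append(sel)
        if best_overall is None or chi < best_overall[1]:
            best_overall = (sel, chi)
    sel_idx = np.concatenate(all_selected)
    uniq, counts = np.unique(sel_idx, return_counts=True)
    weights = counts / counts.sum()
    return EnsembleSelection(
        indices=uniq,
        weights=weights,
        chi2=float(best_overall[1]),
        rg_selected=pool.rg[sel_idx],
        mean_rg_selected=float(pool.rg[sel_idx].mean()),
        mean_rg_pool=float(pool.rg.mean()),
        run_mean_rgs=run_mean_rgs,
    )
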
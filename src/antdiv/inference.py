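"""Scenario templates and composite-likelihood demographic inference.

Ten divergence scenarios between *F. polyctena* (deme ``pol``) and
*F. aquilonia* (deme ``aq``) are expressed as parametric constructors of
:class:`~antdiv.demography.DemographicModel`:

``ALLO``
    Strict divergence: split at ``T_DIV`` from an ancestor of size
    ``N_ANC``; both daughters resize simultaneously at ``T_RESIZE``.
``SYM``
    Divergence with one set of bidirectional migration rates throughout.
``SYM_ASYM``
    Two migration epochs (recent and ancestral, both directions in
    each), switching when the population sizes change.
``IAM`` / ``MAI``
    Isolation after migration (gene flow only before ``T_ISO``) and
    migration after isolation (gene flow only after ``T_MIG``), with the
    resize coinciding with the migration change.
``ALLO10``
    A no-gene-flow control with the same number of free parameters (10)
    as the most complex gene-flow model: asynchronous recent resizes per
    deme plus one extra resize during divergence.
``GHOST_F`` .. ``GHOST_I``
    Three-deme models in which an unsampled ("ghost") lineage splits
    from its sister species at ``T_DG`` and sends migrants into one of
    the focal species; the focal pair exchanges no direct migrants.

Migration parameters are scaled rates 2Nm (haploid migrants per
generation into the forward-time recipient); the per-lineage backward
rate applied to the model is ``2Nm / N_recipient`` with the recipient's
size in the relevant epoch.  Parameter names encode direction in the
forward-time convention: ``M_*_AP`` is gene flow from *aquilonia* into
*polyctena*.

Fitting maximises the composite log10-likelihood
``sum_e m_e log10(p_e)`` over folded-SFS entries (monomorphic cell
included) with a simulation-approximated expected SFS, using
multiple independent runs of a coordinate-cycling multiplicative line
search; common random numbers (one fixed kernel seed per run) make the
objective deterministic within a run.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import (
    GENERATION_TIME_YEARS,
    MU,
    ExpectedSFS,
    expected_sfs,
)
from .demography import DemographicModel, Join, Resize, SetMigration
from .sfs import Folded2DSFS

__all__ = [
    "ParamSpec",
    "ScenarioTemplate",
    "SCENARIOS",
    "build_model",
    "composite_loglik",
    "FitSettings",
    "FitResult",
    "fit_model",
    "compare_models",
    "ScaledParameters",
    "scale_parameters",
    "generations_to_years",
]

P_FLOOR = 1e-20  # probability floor for observed entries unrepresented in simulation

SIZE_RANGE = (1e3, 1e7)  # haploids, log-uniform
TIME_RANGE = (1e2, 1e6)  # generations, uniform initialisation
MIG_RANGE = (1e-10, 20.0)  # 2Nm, log-uniform

POL, AQ, GHOST = "pol", "aq", "ghost"


@dataclass(frozen=True)
class ParamSpec:
    lo: float
    hi: float
    scale: str  # "log" or "linear"


def _sizes(*names):
    return {n: ParamSpec(*SIZE_RANGE, "log") for n in names}


def _times(*names):
    return {n: ParamSpec(*TIME_RANGE, "linear") for n in names}


def _migs(*names):
    return {n: ParamSpec(*MIG_RANGE, "log") for n in names}


@dataclass
class ScenarioTemplate:
    """A named divergence scenario: free parameters, constraints and a
    constructor mapping a parameter vector to a demographic model.

    ``mirrors`` lists parameter permutations (name -> name) that map a
    vector onto a nearly likelihood-equivalent twin (e.g. swapping the
    two migration directions); the fitting stage restarts from these
    twins so that weakly identified orientations are compared at fine
    Monte-Carlo resolution rather than trusted from the coarse search.
    """

    id: str
    params: dict
    order_pairs: list  # (smaller, larger): strict "<" constraints
    builder: object
    mirrors: list = field(default_factory=list)

    @property
    def param_names(self):
        return list(self.params)

    def with_ranges(self, ranges: dict) -> "ScenarioTemplate":
        """Copy of the template with some search ranges overridden.

        ``ranges`` maps parameter name to ``(lo, hi)``; scales are kept.
        """
        params = dict(self.params)
        for name, (lo, hi) in ranges.items():
            if name not in params:
                raise ValueError(f"{self.id}: no parameter {name!r}")
            params[name] = ParamSpec(float(lo), float(hi), params[name].scale)
        return ScenarioTemplate(
            self.id, params, list(self.order_pairs), self.builder,
            list(self.mirrors),
        )

    def validate(self, params: dict) -> None:
        for name, spec in self.params.items():
            if name not in params:
                raise ValueError(f"{self.id}: missing parameter {name!r}")
            v = params[name]
            if not (spec.lo <= v <= spec.hi):
                raise ValueError(
                    f"{self.id}: {name} = {v} outside range [{spec.lo}, {spec.hi}]"
                )
        for a, b in self.order_pairs:
            if not params[a] < params[b]:
                raise ValueError(
                    f"{self.id}: constraint {a} < {b} violated "
                    f"({params[a]} >= {params[b]})"
                )

    def repair(self, params: dict) -> dict:
        """Clip a parameter vector into the feasible region."""
        out = dict(params)
        for name, spec in self.params.items():
            out[name] = float(min(max(out[name], spec.lo), spec.hi))
        # iterate with a shrinking separation epsilon: fixing one ordering
        # can break another in a chain, and members pinned at shared
        # bounds need the upper one raised; shrinking the step guarantees
        # convergence into arbitrarily thin feasible gaps
        eps = 1e-3
        for _ in range(16):
            clean = True
            for a, b in self.order_pairs:
                if out[a] >= out[b]:
                    clean = False
                    out[a] = max(self.params[a].lo, (1.0 - eps) * out[b])
                    if out[a] >= out[b]:  # b pinned at a's lower bound
                        out[b] = min(
                            self.params[b].hi,
                            (1.0 + eps) * max(out[a], out[b]),
                        )
            if clean:
                break
            eps *= 0.5
        if not clean:
            # pathologically thin feasible gaps (upper member barely above
            # a shared lower bound): raise the chain bottom-up instead
            for _ in range(4):
                done = True
                for a, b in self.order_pairs:
                    if out[a] >= out[b]:
                        done = False
                        out[b] = min(
                            self.params[b].hi,
                            max(out[b], out[a]) * (1.0 + 1e-6),
                        )
                        if out[a] >= out[b]:  # b capped at its upper bound
                            out[a] = max(
                                self.params[a].lo, (1.0 - 1e-6) * out[b]
                            )
                if done:
                    break
        return out

    def sample(self, rng: np.random.Generator) -> dict:
        """Draw an initial vector: log-uniform sizes/rates, uniform times."""
        out = {}
        for name, spec in self.params.items():
            if spec.scale == "log":
                out[name] = float(
                    math.exp(rng.uniform(math.log(spec.lo), math.log(spec.hi)))
                )
            else:
                out[name] = float(rng.uniform(spec.lo, spec.hi))
        return self.repair(out)

    def build(self, params: dict, n1: int, n2: int) -> DemographicModel:
        self.validate(params)
        return self.builder(params, n1, n2)


# ----------------------------------------------------------------------
# scenario constructors
# ----------------------------------------------------------------------


def _two_deme(p, n1, n2, mig_recent, mig_ancestral, t_switch, t_div):
    """Shared two-deme skeleton.

    ``mig_recent`` / ``mig_ancestral``: {(from, to): 2Nm} in *forward*
    convention, converted to backward per-lineage rates with the
    recipient's epoch size.
    """
    recent_sizes = {POL: p["N1"], AQ: p["N2"]}
    anc_sizes = {POL: p["N1_ANC"], AQ: p["N2_ANC"]}

    def _rates(m2nm, sizes):
        rates = {}
        for (src, dst), m in m2nm.items():
            if m > 0:
                # forward src -> dst: backward lineages dst -> src
                rates[(dst, src)] = m / sizes[dst]
        return rates

    events = [
        Resize(t_switch, POL, p["N1_ANC"]),
        Resize(t_switch, AQ, p["N2_ANC"]),
        SetMigration(t_switch, _rates(mig_ancestral, anc_sizes)),
        Join(t_div, AQ, POL),
        Resize(t_div, POL, p["N_ANC"]),
        SetMigration(t_div, {}),
    ]
    return DemographicModel(
        demes=[(POL, p["N1"]), (AQ, p["N2"])],
        events=events,
        migration=_rates(mig_recent, recent_sizes),
        sample_config={POL: n1, AQ: n2},
    )


def _build_allo(p, n1, n2):
    return _two_deme(p, n1, n2, {}, {}, p["T_RESIZE"], p["T_DIV"])


def _build_sym(p, n1, n2):
    mig = {(AQ, POL): p["M_AP"], (POL, AQ): p["M_PA"]}
    return _two_deme(p, n1, n2, mig, mig, p["T_RESIZE"], p["T_DIV"])


def _build_sym_asym(p, n1, n2):
    recent = {(AQ, POL): p["M_REC_AP"], (POL, AQ): p["M_REC_PA"]}
    anc = {(AQ, POL): p["M_ANC_AP"], (POL, AQ): p["M_ANC_PA"]}
    return _two_deme(p, n1, n2, recent, anc, p["T_RESIZE"], p["T_DIV"])


def _build_iam(p, n1, n2):
    anc = {(AQ, POL): p["M_ANC_AP"], (POL, AQ): p["M_ANC_PA"]}
    return _two_deme(p, n1, n2, {}, anc, p["T_ISO"], p["T_DIV"])


def _build_mai(p, n1, n2):
    recent = {(AQ, POL): p["M_REC_AP"], (POL, AQ): p["M_REC_PA"]}
    return _two_deme(p, n1, n2, recent, {}, p["T_MIG"], p["T_DIV"])


def _build_allo10(p, n1, n2):
    events = sorted(
        [
            Resize(p["T_R1"], POL, p["N1_MID"]),
            Resize(p["T_R2"], AQ, p["N2_ANC"]),
            Resize(p["T_MID"], POL, p["N1_ANC"]),
        ],
        key=lambda e: e.time,
    ) + [
        Join(p["T_DIV"], AQ, POL),
        Resize(p["T_DIV"], POL, p["N_ANC"]),
    ]
    return DemographicModel(
        demes=[(POL, p["N1"]), (AQ, p["N2"])],
        events=events,
        sample_config={POL: n1, AQ: n2},
    )


def _build_ghost(sister, recipient):
    def build(p, n1, n2):
        t_r, t_dg, t_div = p["T_RESIZE"], p["T_DG"], p["T_DIV"]
        rec_recent = p["N1"] if recipient == POL else p["N2"]
        rec_anc = p["N1_ANC"] if recipient == POL else p["N2_ANC"]
        # backward: recipient lineages move into the ghost
        mig0 = {(recipient, GHOST): p["M_GHOST"] / rec_recent}
        events = []
        if t_r < t_dg:
            events.append(
                SetMigration(t_r, {(recipient, GHOST): p["M_GHOST"] / rec_anc})
            )
        events += [
            Resize(t_r, POL, p["N1_ANC"]),
            Resize(t_r, AQ, p["N2_ANC"]),
            Join(t_dg, GHOST, sister),
            SetMigration(t_dg, {}),
            Join(t_div, AQ, POL),
            Resize(t_div, POL, p["N_ANC"]),
        ]
        events.sort(key=lambda e: e.time)
        return DemographicModel(
            demes=[(POL, p["N1"]), (AQ, p["N2"]), (GHOST, p["N_GHOST"])],
            events=events,
            migration=mig0 if t_dg > 0 else {},
            sample_config={POL: n1, AQ: n2},
        )

    return build


def _ghost_params():
    return {
        **_sizes("N_ANC", "N1_ANC", "N2_ANC", "N1", "N2", "N_GHOST"),
        **_times("T_DIV", "T_RESIZE", "T_DG"),
        **_migs("M_GHOST"),
    }


SCENARIOS = {
    "ALLO": ScenarioTemplate(
        "ALLO",
        {**_sizes("N_ANC", "N1_ANC", "N2_ANC", "N1", "N2"),
         **_times("T_DIV", "T_RESIZE")},
        [("T_RESIZE", "T_DIV")],
        _build_allo,
    ),
    "SYM": ScenarioTemplate(
        "SYM",
        {**_sizes("N_ANC", "N1_ANC", "N2_ANC", "N1", "N2"),
         **_times("T_DIV", "T_RESIZE"), **_migs("M_AP", "M_PA")},
        [("T_RESIZE", "T_DIV")],
        _build_sym,
        mirrors=[{"M_AP": "M_PA", "M_PA": "M_AP"}],
    ),
    "SYM_ASYM": ScenarioTemplate(
        "SYM_ASYM",
        {**_sizes("N_ANC", "N1_ANC", "N2_ANC", "N1", "N2"),
         **_times("T_DIV", "T_RESIZE"),
         **_migs("M_REC_AP", "M_REC_PA", "M_ANC_AP", "M_ANC_PA")},
        [("T_RESIZE", "T_DIV")],
        _build_sym_asym,
        mirrors=[
            {"M_ANC_AP": "M_ANC_PA", "M_ANC_PA": "M_ANC_AP",
             "M_REC_AP": "M_REC_PA", "M_REC_PA": "M_REC_AP"},
        ],
    ),
    "IAM": ScenarioTemplate(
        "IAM",
        {**_sizes("N_ANC", "N1_ANC", "N2_ANC", "N1", "N2"),
         **_times("T_DIV", "T_ISO"), **_migs("M_ANC_AP", "M_ANC_PA")},
        [("T_ISO", "T_DIV")],
        _build_iam,
        mirrors=[{"M_ANC_AP": "M_ANC_PA", "M_ANC_PA": "M_ANC_AP"}],
    ),
    "MAI": ScenarioTemplate(
        "MAI",
        {**_sizes("N_ANC", "N1_ANC", "N2_ANC", "N1", "N2"),
         **_times("T_DIV", "T_MIG"), **_migs("M_REC_AP", "M_REC_PA")},
        [("T_MIG", "T_DIV")],
        _build_mai,
        mirrors=[{"M_REC_AP": "M_REC_PA", "M_REC_PA": "M_REC_AP"}],
    ),
    "ALLO10": ScenarioTemplate(
        "ALLO10",
        {**_sizes("N_ANC", "N1_ANC", "N1_MID", "N2_ANC", "N1", "N2"),
         **_times("T_DIV", "T_MID", "T_R1", "T_R2")},
        [("T_R1", "T_MID"), ("T_MID", "T_DIV"), ("T_R2", "T_DIV")],
        _build_allo10,
    ),
    "GHOST_F": ScenarioTemplate(
        "GHOST_F", _ghost_params(),
        [("T_RESIZE", "T_DIV"), ("T_DG", "T_DIV")],
        _build_ghost(sister=POL, recipient=POL),
    ),
    "GHOST_G": ScenarioTemplate(
        "GHOST_G", _ghost_params(),
        [("T_RESIZE", "T_DIV"), ("T_DG", "T_DIV")],
        _build_ghost(sister=POL, recipient=AQ),
    ),
    "GHOST_H": ScenarioTemplate(
        "GHOST_H", _ghost_params(),
        [("T_RESIZE", "T_DIV"), ("T_DG", "T_DIV")],
        _build_ghost(sister=AQ, recipient=AQ),
    ),
    "GHOST_I": ScenarioTemplate(
        "GHOST_I", _ghost_params(),
        [("T_RESIZE", "T_DIV"), ("T_DG", "T_DIV")],
        _build_ghost(sister=AQ, recipient=POL),
    ),
}


def build_model(
    scenario_id: str, params: dict, n1: int, n2: int, ranges: dict | None = None
) -> DemographicModel:
    """Instantiate a scenario's demographic model from a parameter vector.

    ``ranges`` optionally widens/narrows per-parameter search ranges
    (values must lie inside their range as well as satisfy the time
    orderings).
    """
    if scenario_id not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario_id!r}")
    template = SCENARIOS[scenario_id]
    if ranges:
        template = template.with_ranges(ranges)
    return template.build(params, n1, n2)


# ----------------------------------------------------------------------
# composite likelihood
# ----------------------------------------------------------------------


def composite_loglik(obs: Folded2DSFS, exp: ExpectedSFS) -> float:
    """Composite log10-likelihood of an observed folded SFS.

    ``sum_e m_e log10(p_e)`` over folded entries with the monomorphic
    mass pooled into the (0, 0) cell on both sides; expected
    probabilities for observed-but-unsimulated entries are floored at
    1e-20.
    """
    if (exp.n1, exp.n2) != (obs.n1, obs.n2):
        raise ValueError(
            f"sample-size mismatch: expected SFS is ({exp.n1}, {exp.n2}), "
            f"observed is ({obs.n1}, {obs.n2})"
        )
    p = exp.folded()
    p[0, 0] += exp.p_mono
    m = obs.counts.astype(np.float64).copy()
    m[0, 0] += obs.monomorphic
    mask = m > 0
    return float((m[mask] * np.log10(np.maximum(p[mask], P_FLOOR))).sum())


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------


@dataclass
class FitSettings:
    """Search effort knobs; defaults follow the full-scale protocol
    (100 runs, 80 iterations, 200,000 genealogies per evaluation).

    When ``refine_top > 0``, the best stage-1 runs are re-optimised with
    ``refine_sims`` genealogies per evaluation (finer Monte-Carlo
    resolution, smaller initial step) and the final estimate is chosen
    among the refined runs; this mirrors the common coarse-then-fine
    practice for simulation-based composite likelihoods.
    """

    n_runs: int = 100
    n_iters: int = 80
    n_sims: int = 200_000
    rng_seed: int = 0
    refine_top: int = 0
    refine_iters: int = 10
    refine_sims: int = 0
    final_sims: int = 0  # optional high-precision polish of the leaders
    final_iters: int = 6
    final_top: int = 1  # how many refined leaders enter the final polish
    max_polish_starts: int = 0  # cap on refinement starts (0 = no cap)
    step_start: float = 3.0  # initial multiplicative step of the line search
    smart_init: bool = True  # centre initial points on the data's diversity scale

    def to_dict(self):
        return {
            "n_runs": self.n_runs,
            "n_iters": self.n_iters,
            "n_sims": self.n_sims,
            "rng_seed": self.rng_seed,
            "refine_top": self.refine_top,
            "refine_iters": self.refine_iters,
            "refine_sims": self.refine_sims,
            "final_sims": self.final_sims,
            "final_iters": self.final_iters,
            "max_polish_starts": self.max_polish_starts,
            "step_start": self.step_start,
            "smart_init": self.smart_init,
        }


@dataclass
class RunRecord:
    run: int
    kernel_seed: int
    init: dict
    params: dict
    lnCL: float
    n_evals: int


@dataclass
class FitResult:
    """Best-run parameter vector with full per-run provenance."""

    scenario: str
    params: dict
    lnCL: float
    runs: list
    settings: dict
    n1: int
    n2: int
    obs_signature: tuple

    def to_json(self, path=None) -> str:
        payload = {
            "scenario": self.scenario,
            "params": self.params,
            "lnCL": self.lnCL,
            "n1": self.n1,
            "n2": self.n2,
            "obs_signature": list(self.obs_signature),
            "settings": self.settings,
            "runs": [
                {
                    "run": r.run,
                    "kernel_seed": r.kernel_seed,
                    "init": r.init,
                    "params": r.params,
                    "lnCL": r.lnCL,
                    "n_evals": r.n_evals,
                }
                for r in self.runs
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FitResult":
        if isinstance(source, (str, bytes)) and "\n" not in str(source) and str(source).endswith(".json"):
            with open(source) as fh:
                payload = json.load(fh)
        else:
            payload = json.loads(source)
        runs = [RunRecord(**r) for r in payload["runs"]]
        return cls(
            scenario=payload["scenario"],
            params=payload["params"],
            lnCL=payload["lnCL"],
            runs=runs,
            settings=payload["settings"],
            n1=payload["n1"],
            n2=payload["n2"],
            obs_signature=tuple(payload["obs_signature"]),
        )


def _rough_size_scale(obs: Folded2DSFS, mu: float) -> float:
    """Watterson-style haploid-size scale from the observed spectrum.

    Treats the pooled sample as panmictic: the polymorphic fraction is
    ``mu * E[total length]`` and ``E[total length] = 2 N h_{n-1}``; used
    only to centre initial search points, never to constrain bounds.
    """
    s_poly = float(obs.counts.sum() - obs.counts[0, 0])
    total = float(obs.counts.sum() + obs.monomorphic)
    if s_poly <= 0 or total <= 0:
        return float(np.sqrt(SIZE_RANGE[0] * SIZE_RANGE[1]))
    p_poly = s_poly / total
    n = obs.n1 + obs.n2
    hn = sum(1.0 / i for i in range(1, max(2, n)))
    return p_poly / (mu * 2.0 * hn)


def _init_template(template, obs, mu, spread=30.0):
    """Template copy whose size/time ranges are centred on the rough
    diversity scale of the data (initial points only)."""
    nr = _rough_size_scale(obs, mu)
    ranges = {}
    for name, spec in template.params.items():
        if name.startswith("N"):
            lo = max(spec.lo, nr / spread)
            hi = min(spec.hi, nr * spread)
        elif name.startswith("T"):
            lo = max(spec.lo, 0.02 * nr)
            hi = min(spec.hi, 20.0 * nr)
        else:
            continue
        if lo < hi:
            ranges[name] = (lo, hi)
    return template.with_ranges(ranges)


def _stratify_migration(params: dict, template, rng, run: int) -> dict:
    """Force initial migration magnitudes through a 4-cycle of regimes.

    Log-uniform initial draws over [1e-10, 20] put almost every start in
    the effectively-zero-gene-flow regime; cycling starts through
    (as-drawn / one direction strong / other direction strong / both
    strong) guarantees that qualitatively different gene-flow modes are
    all visited, leaving the data to rank them.
    """
    pattern = run % 4
    if pattern == 0:
        return params
    out = dict(params)

    def _lu(lo, hi):
        return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))

    mig_names = [n for n in template.params if n.startswith("M")]
    pairs = {}
    singles = []
    for n in mig_names:
        if n.endswith("_AP") or n.endswith("_PA"):
            pairs.setdefault(n[:-3], {})[n[-2:]] = n
        else:
            singles.append(n)
    for stem, d in pairs.items():
        if len(d) != 2:
            singles.extend(d.values())
            continue
        if pattern == 1:
            out[d["AP"]] = _lu(0.05, 10.0)
            out[d["PA"]] = _lu(1e-10, 1e-2)
        elif pattern == 2:
            out[d["PA"]] = _lu(0.05, 10.0)
            out[d["AP"]] = _lu(1e-10, 1e-2)
        else:
            out[d["AP"]] = _lu(0.05, 10.0)
            out[d["PA"]] = _lu(0.05, 10.0)
    for n in singles:
        out[n] = _lu(0.05, 10.0) if pattern in (1, 3) else _lu(1e-10, 1e-2)
    return template.repair(out)


def _rough_divergence_time(obs: Folded2DSFS, mu: float) -> float:
    """Moment anchor for the divergence time from fixed differences.

    Sites whose pooled minor allele occupies all copies of one
    population are (mostly) fixed differences; their share of
    polymorphic sites is roughly ``2 T / E[total length]`` under deep
    divergence, giving ``T ≈ f_fix × E[L] / 2`` with ``E[L]`` estimated
    from the polymorphic fraction.  Used only to place starting points.
    """
    s_poly = float(obs.counts.sum() - obs.counts[0, 0])
    total = float(obs.counts.sum() + obs.monomorphic)
    if s_poly <= 0 or total <= 0:
        return 0.0
    f_fix = float(obs.counts[obs.n1, 0] + obs.counts[0, obs.n2]) / s_poly
    l_hat = (s_poly / total) / mu
    return 0.5 * f_fix * l_hat


def _anchored_starts(template, obs, mu) -> list:
    """Deterministic refinement starts at the data's diversity scale.

    Sizes sit at the Watterson-style scale, the divergence time at the
    larger of one coalescent unit and the fixed-difference moment
    anchor, other times at a fraction; the migration block cycles
    through the qualitative gene-flow regimes.  These collapse the long
    size/time ridges that random stage-1 descents can wander along.
    """
    nr = _rough_size_scale(obs, mu)
    t_anchor = max(nr, _rough_divergence_time(obs, mu))
    base = {}
    for name, spec in template.params.items():
        if name.startswith("N"):
            base[name] = nr
        elif name == "T_DIV":
            base[name] = t_anchor
        elif name.startswith("T"):
            base[name] = 0.15 * nr
    mig_names = [n for n in template.params if n.startswith("M")]
    if not mig_names:
        return [template.repair(base)]
    strong, weak = 1.0, 1e-8
    has_pairs = any(n.endswith(("_AP", "_PA")) for n in mig_names)
    has_epochs = any("ANC" in n for n in mig_names) and any(
        "ANC" not in n for n in mig_names
    )
    patterns = ["off"]
    if has_pairs:
        patterns += ["ap", "pa"]
    patterns += ["all"]
    if has_pairs and has_epochs:
        # ancestral-epoch-only gene flow, per direction
        patterns += ["anc_ap", "anc_pa"]
    starts = []
    seen = set()
    for pattern in patterns:
        cand = dict(base)
        for n in mig_names:
            on = (
                pattern == "all"
                or (pattern == "ap" and n.endswith("_AP"))
                or (pattern == "pa" and n.endswith("_PA"))
                or (pattern == "anc_ap" and "ANC" in n and n.endswith("_AP"))
                or (pattern == "anc_pa" and "ANC" in n and n.endswith("_PA"))
            )
            cand[n] = strong if on else weak
        cand = template.repair(cand)
        key = tuple(sorted(cand.items()))
        if key not in seen:
            seen.add(key)
            starts.append(cand)
    return starts


def _objective(template, params, obs, n_sims, kernel_seed, mu):
    model = template.build(params, obs.n1, obs.n2)
    exp = expected_sfs(model, n_sims, kernel_seed, mu=mu)
    return composite_loglik(obs, exp)


def _polish_scale(template, params, obs, n_sims, kernel_seed, mu):
    """Line search along the global coalescent-scale direction.

    Multiplying every size and time by a common factor rescales the
    whole history; the composite likelihood is far more curved along
    this direction (it sets the absolute polymorphism level against the
    monomorphic mass) than along the shape ridges, so snapping it first
    speeds up the local polish considerably.
    """
    scaled_names = [n for n in template.param_names if n[0] in "NT"]
    best = _objective(template, params, obs, n_sims, kernel_seed, mu)
    n_evals = 1
    for half_width in (0.10, 0.03):
        grid = np.exp(np.linspace(-half_width, half_width, 7))
        for lam in grid:
            if lam == 1.0:
                continue
            cand = template.repair(
                {
                    k: (v * lam if k in scaled_names else v)
                    for k, v in params.items()
                }
            )
            val = _objective(template, cand, obs, n_sims, kernel_seed, mu)
            n_evals += 1
            if val > best:
                best = val
                params = cand
    return params, best, n_evals


def _polish_simplex(template, params, obs, n_sims, kernel_seed, mu,
                    maxfev=300, scale=0.05):
    """Nelder-Mead refinement in log10 parameter space.

    The common-random-number objective is deterministic, so a simplex
    search is well posed; its diagonal moves traverse correlated ridges
    (e.g. divergence time versus migration rate) that axis-aligned line
    searches stall on.  ``scale`` sets the initial simplex size in
    log10 units; keep it small for a local polish so the simplex cannot
    wander along near-flat ridges into a neighbouring mode.
    """
    from scipy.optimize import minimize

    names = template.param_names
    x0 = np.log10([params[n] for n in names])

    def neg(x):
        cand = template.repair({n: float(10.0**v) for n, v in zip(names, x)})
        return -_objective(template, cand, obs, n_sims, kernel_seed, mu)

    res = minimize(
        neg, x0, method="Nelder-Mead",
        options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 0.05,
                 "initial_simplex": x0 + scale * np.eye(len(names) + 1,
                                                        len(names), k=-1)},
    )
    best = template.repair({n: float(10.0**v) for n, v in zip(names, res.x)})
    if -float(res.fun) < _objective(template, params, obs, n_sims, kernel_seed, mu):
        # never accept a polish that ends below its start
        return dict(params), _objective(
            template, params, obs, n_sims, kernel_seed, mu
        ), int(res.nfev)
    return best, -float(res.fun), int(res.nfev)


def _optimize(template, params, obs, n_iters, n_sims, kernel_seed, mu, f_start=3.0):
    """Coordinate-cycling multiplicative line search; deterministic given
    the kernel seed (common random numbers)."""
    names = template.param_names
    best = _objective(template, params, obs, n_sims, kernel_seed, mu)
    n_evals = 1
    decay = (1.02 / f_start) ** (1.0 / max(1, n_iters - 1))
    for it in range(n_iters):
        f = f_start * decay**it
        improved = False
        for name in names:
            moved = False
            for direction in (f, 1.0 / f):
                while True:
                    cand = template.repair({**params, name: params[name] * direction})
                    if cand[name] == params[name]:
                        break
                    val = _objective(template, cand, obs, n_sims, kernel_seed, mu)
                    n_evals += 1
                    if val > best:
                        best = val
                        params = cand
                        improved = True
                        moved = True
                    else:
                        break
                if moved:
                    break
        if not improved and f <= 1.05:
            break
    return params, best, n_evals


def fit_model(
    obs: Folded2DSFS,
    scenario_id: str,
    settings: FitSettings | None = None,
    inits: list | None = None,
    ranges: dict | None = None,
    mu: float = MU,
) -> FitResult:
    """Maximise the composite likelihood of a scenario on an observed SFS.

    Each run draws an independent starting point (or uses ``inits``),
    fixes one kernel seed (common random numbers make the per-run
    objective deterministic), and cycles multiplicative line searches
    over the parameters with a geometrically shrinking step.  The best
    run wins.  Fully reproducible given ``settings.rng_seed``.
    """
    settings = settings or FitSettings()
    template = SCENARIOS[scenario_id]
    if ranges:
        template = template.with_ranges(ranges)
    names = template.param_names
    init_template = (
        _init_template(template, obs, mu) if settings.smart_init else template
    )
    runs: list[RunRecord] = []
    any_finite = False
    for run in range(settings.n_runs):
        ss = np.random.SeedSequence([settings.rng_seed & 0x7FFFFFFF, run])
        s0, s1 = ss.generate_state(2)
        kernel_seed = int(s0 % (2**31))
        rng = np.random.default_rng(int(s1))
        if inits is not None:
            params = template.repair(dict(inits[run % len(inits)]))
        else:
            params = template.repair(init_template.sample(rng))
            if settings.smart_init:
                params = _stratify_migration(params, template, rng, run)
        init = dict(params)
        params, best, n_evals = _optimize(
            template, params, obs, settings.n_iters, settings.n_sims,
            kernel_seed, mu, f_start=settings.step_start,
        )
        if math.isfinite(best):
            any_finite = True
        runs.append(
            RunRecord(
                run=run,
                kernel_seed=kernel_seed,
                init=init,
                params=params,
                lnCL=best,
                n_evals=n_evals,
            )
        )
    if not any_finite:
        raise RuntimeError(
            "non-finite composite likelihood at every initialisation; "
            "check search-range configuration"
        )
    if settings.refine_top > 0 and settings.refine_sims > 0:
        top = sorted(runs, key=lambda r: -r.lnCL)[: settings.refine_top]
        starts = []
        for rec in top:
            starts.append(dict(rec.params))
            for mirror in template.mirrors:
                twin = dict(rec.params)
                for src, dst in mirror.items():
                    twin[dst] = rec.params[src]
                starts.append(template.repair(twin))
        if settings.smart_init:
            starts.extend(_anchored_starts(template, obs, mu))
        if settings.max_polish_starts > 0:
            starts = starts[: settings.max_polish_starts]
        # one shared kernel seed per phase: objectives are common-random-
        # number comparable across starting points
        ss = np.random.SeedSequence([settings.rng_seed & 0x7FFFFFFF, settings.n_runs])
        kseed_coarse, kseed = (int(s % (2**31)) for s in ss.generate_state(2))
        # coarse within-basin polish of every start (mirrored and anchored
        # starts carry companion parameters far from their basin optimum;
        # the coarse objective is cheap, so run it full-length)
        polished = []
        for init_params in starts:
            params, val, e1 = _optimize(
                template, dict(init_params), obs, settings.n_iters,
                settings.n_sims, kseed_coarse, mu, f_start=2.5,
            )
            polished.append((val, params, dict(init_params), e1))
        polished.sort(key=lambda t: -t[0])
        refined = []
        for j, (_, params, init_params, e1) in enumerate(
            polished[: max(1, settings.refine_top + 1)]
        ):
            params, _, e_nm = _polish_simplex(
                template, params, obs, settings.n_sims, kseed_coarse, mu,
                maxfev=60 * settings.refine_iters, scale=0.05,
            )
            e1 += e_nm
            params, best, e2 = _optimize(
                template, params, obs, settings.refine_iters,
                settings.refine_sims, kseed, mu, f_start=1.3,
            )
            refined.append(
                RunRecord(
                    run=settings.n_runs + j,
                    kernel_seed=kseed,
                    init=init_params,
                    params=params,
                    lnCL=best,
                    n_evals=e1 + e2,
                )
            )
        runs.extend(refined)
        # stage-2 objectives use more genealogies: compare only among them
        best_run = max(refined, key=lambda r: r.lnCL)
    else:
        best_run = max(runs, key=lambda r: r.lnCL)
    if settings.final_sims > 0:
        # high-precision polish of the leading candidates under shared
        # kernel seeds: a scale snap, a long simplex at a third of the
        # genealogy count (most of the convergence for a fraction of the
        # cost), and a tight simplex at full count.  When two leaders are
        # available, their per-parameter geometric mean is polished too:
        # flanking modes of a likelihood ridge often bracket the optimum.
        pool = sorted(
            (refined if settings.refine_top > 0 and settings.refine_sims > 0
             else runs),
            key=lambda r: -r.lnCL,
        )
        starts = [dict(pool[0].params)]
        if settings.final_top >= 2 and len(pool) > 1:

            def _dist(a, b):
                return max(
                    abs(math.log10(max(a[k], 1e-300) / max(b[k], 1e-300)))
                    for k in template.param_names
                )

            second = max(pool[1:], key=lambda r: _dist(r.params, pool[0].params))
            starts.append(dict(second.params))
            mid = template.repair(
                {
                    k: math.sqrt(pool[0].params[k] * second.params[k])
                    for k in template.param_names
                }
            )
            starts.append(mid)
        ss = np.random.SeedSequence(
            [settings.rng_seed & 0x7FFFFFFF, settings.n_runs + 1000]
        )
        kseed_mid, kseed = (int(s % (2**31)) for s in ss.generate_state(2))
        mid_sims = max(settings.final_sims // 3, settings.n_sims)
        finals = []
        for start in starts:
            params, _, e1 = _polish_scale(
                template, dict(start), obs, settings.final_sims, kseed, mu,
            )
            params, _, e2 = _polish_simplex(
                template, params, obs, mid_sims, kseed_mid, mu,
                maxfev=120 * settings.final_iters, scale=0.05,
            )
            params, best, e3 = _polish_simplex(
                template, params, obs, settings.final_sims, kseed, mu,
                maxfev=30 * settings.final_iters, scale=0.015,
            )
            finals.append(
                RunRecord(
                    run=len(runs) + len(finals),
                    kernel_seed=kseed,
                    init=dict(start),
                    params=params,
                    lnCL=best,
                    n_evals=e1 + e2 + e3,
                )
            )
        runs.extend(finals)
        best_run = max(finals, key=lambda r: r.lnCL)
    return FitResult(
        scenario=scenario_id,
        params=dict(best_run.params),
        lnCL=best_run.lnCL,
        runs=runs,
        settings=settings.to_dict(),
        n1=obs.n1,
        n2=obs.n2,
        obs_signature=obs.signature(),
    )


def compare_models(fits) -> pd.DataFrame:
    """Rank fitted scenarios by composite likelihood.

    No AIC/BIC is computed: with linked sites the composite likelihood
    is valid for point estimation but not for information-criterion
    penalties.  Ties are broken by scenario id for a stable order.
    """
    fits = list(fits)
    sigs = {f.obs_signature for f in fits}
    if len(sigs) > 1:
        raise ValueError("fits compare different observed spectra")
    rows = sorted(fits, key=lambda f: (-f.lnCL, f.scenario))
    best = rows[0].lnCL
    return pd.DataFrame(
        {
            "scenario": [f.scenario for f in rows],
            "lnCL": [f.lnCL for f in rows],
            "delta_lnCL": [best - f.lnCL for f in rows],
            "n_params": [len(SCENARIOS[f.scenario].param_names) for f in rows],
        }
    )


# ----------------------------------------------------------------------
# natural-unit scaling
# ----------------------------------------------------------------------


@dataclass
class ScaledParameters:
    """Parameter estimates in natural units.

    Times in years are generations times the generation time (2.5 years),
    rounded to the nearest integer for reporting; sizes are haploid gene
    copies; migration is reported as 2Nm per forward-time direction.
    """

    scenario: str
    sizes_haploid: dict
    times_generations: dict
    times_years: dict
    mig_2nm: dict
    mu: float
    generation_time_years: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, v in self.sizes_haploid.items():
            rows.append((k, "haploids", v))
        for k, v in self.times_generations.items():
            rows.append((k, "generations", v))
        for k, v in self.times_years.items():
            rows.append((k, "years", v))
        for k, v in self.mig_2nm.items():
            rows.append((k, "2Nm", v))
        return pd.DataFrame(rows, columns=["parameter", "unit", "estimate"])


def generations_to_years(
    generations: float, gen_time_years: float = GENERATION_TIME_YEARS
) -> int:
    """Convert a time in generations to years.

    Reported values are rounded half-up to the nearest year (so 0.5-year
    halves from odd generation counts round upward).
    """
    return int(math.floor(generations * gen_time_years + 0.5))


def scale_parameters(
    fit: FitResult,
    mu: float = MU,
    gen_time_years: float = GENERATION_TIME_YEARS,
) -> ScaledParameters:
    """Scale a fitted parameter vector to years / haploids / 2Nm."""
    sizes, tg, ty, mig = {}, {}, {}, {}
    for name, v in fit.params.items():
        if name.startswith("N"):
            sizes[name] = float(v)
        elif name.startswith("T"):
            tg[name] = float(v)
            ty[name] = generations_to_years(v, gen_time_years)
        elif name.startswith("M"):
            mig[name] = float(v)
    return ScaledParameters(
        scenario=fit.scenario,
        sizes_haploid=sizes,
        times_generations=tg,
        times_years=ty,
        mig_2nm=mig,
        mu=mu,
        generation_time_years=gen_time_years,
    )
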
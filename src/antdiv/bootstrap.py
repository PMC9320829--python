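"""Nonparametric block-bootstrap confidence intervals for fitted parameters.

Linked sites make per-site resampling invalid, so uncertainty is
assessed by resampling whole 50-kb windows with replacement from the
complete-data (window-resampled) table, rebuilding the folded joint SFS
for each replicate, and refitting the scenario starting from the
maximum-likelihood estimates (first run exactly at the MLE, further
runs at lognormally jittered copies, sigma = 0.25 on the log scale).
Percentile intervals are reported; with fewer than 1000 replicates the
result is flagged as indicative only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import SCENARIOS, FitResult, FitSettings, fit_model
from .sfs import Folded2DSFS, ResampledData, attach_monomorphic, build_folded_sfs

__all__ = ["BootstrapResult", "block_bootstrap_dataset", "bootstrap_cis"]


@dataclass
class BootstrapResult:
    """Per-parameter percentile confidence intervals from block bootstrap."""

    scenario: str
    point: dict
    level: float
    lower: dict
    upper: dict
    replicates: pd.DataFrame  # one row per replicate, one column per parameter
    settings: dict = field(default_factory=dict)
    indicative: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.point:
            rows.append(
                {
                    "parameter": name,
                    "estimate": self.point[name],
                    "lower": self.lower[name],
                    "upper": self.upper[name],
                    "level": self.level,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def block_bootstrap_dataset(
    data: ResampledData, rng_seed: int, draw=None
) -> ResampledData:
    """Resample the windows of a complete-data table with replacement.

    Draws W windows (with replacement) from the W windows present and
    concatenates their sites; deterministic given ``rng_seed``.  An
    explicit ``draw`` (sequence of window ids) overrides the random
    draw, e.g. the identity permutation reproduces the observed data.
    """
    wins = np.unique(data.window)
    W = wins.size
    if W == 0:
        raise ValueError("no windows to resample")
    if draw is None:
        rng = np.random.default_rng(rng_seed)
        draw = rng.choice(wins, size=W, replace=True)
    else:
        draw = np.asarray(draw)
    parts = [np.flatnonzero(data.window == w) for w in draw]
    idx = np.concatenate(parts) if parts else np.array([], dtype=np.int64)
    new_window = np.concatenate(
        [np.full(p.size, k, dtype=np.int64) for k, p in enumerate(parts)]
    ) if parts else np.array([], dtype=np.int64)
    return ResampledData(
        chrom=data.chrom[idx],
        pos=data.pos[idx],
        window=new_window,
        c1=data.c1[idx],
        c2=data.c2[idx],
        n1=data.n1,
        n2=data.n2,
        pop1=data.pop1,
        pop2=data.pop2,
        n_snps_input=data.n_snps_input,
        selection=dict(data.selection, bootstrap_seed=rng_seed,
                       bootstrap_draw=draw.tolist()),
    )


def _bootstrap_sfs(resampled: ResampledData, obs: Folded2DSFS) -> Folded2DSFS:
    """SFS of a bootstrap resample; monomorphic count rescaled
    proportionally to the resampled SNP total."""
    sfs = build_folded_sfs(resampled)
    s_obs = int(obs.counts.sum())
    s_boot = int(sfs.counts.sum())
    mono = int(round(obs.monomorphic * s_boot / s_obs)) if s_obs else 0
    return Folded2DSFS(
        counts=sfs.counts,
        monomorphic=mono,
        n1=sfs.n1,
        n2=sfs.n2,
        provenance=dict(sfs.provenance, bootstrap=True),
    )


def bootstrap_cis(
    data: ResampledData,
    obs: Folded2DSFS,
    mle: FitResult,
    n_replicates: int = 100,
    runs_per_rep: int = 10,
    n_iters: int = 20,
    n_sims: int = 20_000,
    level: float = 0.99,
    rng_seed: int = 0,
    jitter_sigma: float = 0.25,
) -> BootstrapResult:
    """Percentile block-bootstrap confidence intervals around an MLE.

    Each replicate resamples windows, rebuilds the SFS and refits the
    scenario with ``runs_per_rep`` runs initialised at the MLE (run 0)
    or at multiplicative lognormal jitters of it.  CI endpoints at level
    ``q`` are the ``(1-q)/2`` and ``1-(1-q)/2`` percentiles of the
    replicate best-run estimates (e.g. 0.5th and 99.5th for 99%).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    template = SCENARIOS[mle.scenario]
    names = template.param_names
    root = np.random.SeedSequence(rng_seed & 0x7FFFFFFF)
    rows = []
    dropped = 0
    rep_seeds = root.generate_state(n_replicates)
    for rep in range(n_replicates):
        boot_seed = int(rep_seeds[rep] % (2**31))
        resampled = block_bootstrap_dataset(data, boot_seed)
        sfs_b = _bootstrap_sfs(resampled, obs)
        # the refit seed is a function of the resampled data itself:
        # identical resamples give bit-identical estimates (degenerate
        # one-window data yields exactly zero-width intervals), while
        # distinct resamples get fresh search randomness so the
        # replicate estimates explore flat likelihood ridges the way
        # independent full fits would
        draw = tuple(sorted(resampled.selection["bootstrap_draw"]))
        fit_seed = int(
            np.random.SeedSequence(
                [rng_seed & 0x7FFFFFFF, *draw]
            ).generate_state(1)[0]
            % (2**31)
        )
        jrng = np.random.default_rng(fit_seed)
        inits = [dict(mle.params)]
        for _ in range(runs_per_rep - 1):
            inits.append(
                {
                    k: v * float(np.exp(jrng.normal(0.0, jitter_sigma)))
                    for k, v in mle.params.items()
                }
            )
        fit = fit_model(
            sfs_b,
            mle.scenario,
            FitSettings(
                n_runs=runs_per_rep,
                n_iters=n_iters,
                n_sims=n_sims,
                rng_seed=fit_seed,
                step_start=1.4,  # refits start at the MLE: small moves suffice
                final_sims=n_sims,  # simplex polish tracks the resampled data
                final_iters=2,
                final_top=1,
            ),
            inits=inits,
        )
        if not np.isfinite(fit.lnCL):
            dropped += 1
            continue
        rows.append(
            {"replicate": rep, "boot_seed": boot_seed, "fit_seed": fit_seed,
             "lnCL": fit.lnCL, **fit.params}
        )
    if not rows:
        raise RuntimeError("all bootstrap replicates failed to fit")
    reps = pd.DataFrame(rows)
    alpha = (1.0 - level) / 2.0
    lower, upper = {}, {}
    for name in names:
        lo, hi = np.percentile(reps[name], [100 * alpha, 100 * (1 - alpha)])
        lower[name] = float(lo)
        upper[name] = float(hi)
    return BootstrapResult(
        scenario=mle.scenario,
        point=dict(mle.params),
        level=level,
        lower=lower,
        upper=upper,
        replicates=reps,
        settings={
            "n_replicates": n_replicates,
            "runs_per_rep": runs_per_rep,
            "n_iters": n_iters,
            "n_sims": n_sims,
            "rng_seed": rng_seed,
            "jitter_sigma": jitter_sigma,
            "window_bp": data.selection.get("window_bp"),
            "replicates_dropped": dropped,
        },
        indicative=n_replicates < 1000,
    )
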
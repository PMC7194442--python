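"""Adaptive Metropolis-within-Gibbs sampling of the posterior.

Parameters are updated in blocks: the fixed effects alpha as one random-walk
block; the spline coefficients phi in spatially contiguous sub-blocks
(super-cells of the knot grid) so acceptance stays workable at Q in the
hundreds; the region effects psi as one block whose proposals are projected
onto the sum-to-zero subspace of each connected component (the identifiable
part of the intrinsic CAR — the overall level is absorbed by the
intercept); and each precision scale by a log-scale random-walk step (the
IG prior on the *precision* is not conjugate to the CAR quadratic form, so
no Gibbs draw exists for it).

Two adaptation mechanisms run during burn-in only, and are frozen
afterwards so the retained chain is a genuine Markov chain with the
posterior invariant:

* Robbins-Monro tuning of each block's proposal magnitude toward a 0.234
  acceptance target for multivariate blocks and 0.44 for scalars;
* empirical-covariance (Haario-style) proposal shaping per multivariate
  block, engaged once enough burn-in history has accumulated.

Because the wetland-cover surface multiplies a covariate with nonzero
mean, the common level of phi is strongly (though not perfectly) aliased
with the intercept, which makes naive per-block updates of phi mix very
slowly.  The sampler therefore reparameterizes phi = b + phi~ where b is a
global wetland slope and phi~ sums to zero: b joins the alpha block (whose
shaped covariance learns the intercept-slope correlation and proposes
along the ridge), while phi~ proposals are re-centered to stay in the
sum-to-zero subspace.  The map (b, phi~) -> phi is linear and the ICAR
prior is invariant to the level split, so this changes nothing about the
posterior over phi — only how it is explored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelSpec, ParameterState, log_posterior_safe


@dataclass
class SamplerConfig:
    """Run-length, seeding, blocking and adaptation settings."""

    n_iterations: int = 15000
    n_burnin: int = 10000
    seed: int = 0
    thinning: int = 1
    phi_block_size: int = 4          # super-cells of knot-grid cells
    target_accept_multi: float = 0.234
    target_accept_scalar: float = 0.44
    initial_scale: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.n_burnin < self.n_iterations:
            raise ValueError("need 0 <= n_burnin < n_iterations")
        if not (0 < self.target_accept_multi < 1
                and 0 < self.target_accept_scalar < 1):
            raise ValueError("target acceptance rates must be in (0, 1)")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class Chain:
    """Retained posterior draws plus bookkeeping."""

    draws: np.ndarray                # (n_retained, dim)
    names: list[str]
    acceptance: dict[str, float]     # post-burn-in rate per block
    seed: int
    config: SamplerConfig

    def __post_init__(self) -> None:
        if not np.isfinite(self.draws).all():
            raise ValueError("chain contains non-finite draws")

    @property
    def n_retained(self) -> int:
        return self.draws.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.names)

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]

    def save(self, directory: str | Path) -> None:
        """Persist as a columnar CSV plus a JSON metadata sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(directory / "chain.csv", index=False)
        meta = {
            "seed": self.seed,
            "acceptance": self.acceptance,
            "n_iterations": self.config.n_iterations,
            "n_burnin": self.config.n_burnin,
            "thinning": self.config.thinning,
        }
        (directory / "chain_meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, directory: str | Path) -> "Chain":
        directory = Path(directory)
        df = pd.read_csv(directory / "chain.csv")
        meta = json.loads((directory / "chain_meta.json").read_text())
        cfg = SamplerConfig(n_iterations=meta["n_iterations"],
                            n_burnin=meta["n_burnin"],
                            seed=meta["seed"],
                            thinning=meta["thinning"])
        return cls(draws=df.to_numpy(), names=list(df.columns),
                   acceptance=meta["acceptance"], seed=meta["seed"],
                   config=cfg)


class _Block:
    """One Metropolis block: scale adaptation + covariance shaping."""

    #: burn-in samples required before the empirical covariance engages
    COV_WARMUP = 200

    def __init__(self, name: str, dim: int, scale: float, target: float,
                 shape_cov: bool = False):
        self.name = name
        self.dim = dim
        self.log_scale = np.log(scale)
        self.target = target
        self.shape_cov = shape_cov and dim > 1
        self.accepted = 0
        self.proposed = 0
        self._mean = np.zeros(dim)
        self._m2 = np.zeros((dim, dim)) if self.shape_cov else None
        self._count = 0
        self._chol: np.ndarray | None = None

    def noise(self, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.dim)
        if self._chol is not None:
            return float(np.exp(self.log_scale)) * (self._chol @ z)
        return float(np.exp(self.log_scale)) * z

    def record(self, x: np.ndarray) -> None:
        """Accumulate burn-in history for covariance shaping."""
        if not self.shape_cov:
            return
        self._count += 1
        d = x - self._mean
        self._mean += d / self._count
        self._m2 += np.outer(d, x - self._mean)
        if self._count >= self.COV_WARMUP and self._count % 50 == 0:
            cov = self._m2 / (self._count - 1)
            jitter = 1e-10 + 1e-6 * np.trace(cov) / self.dim
            try:
                chol = np.linalg.cholesky(cov + jitter * np.eye(self.dim))
            except np.linalg.LinAlgError:
                return
            if self._chol is None:
                # switch from isotropic to shaped: restart the magnitude
                # at the Roberts-Rosenthal optimum 2.38/sqrt(d)
                self.log_scale = np.log(2.38 / np.sqrt(self.dim))
            self._chol = chol

    def adapt(self, accept_prob: float, t: int) -> None:
        gamma = (t + 10.0) ** -0.6
        self.log_scale += gamma * (accept_prob - self.target)

    def reset_stats(self) -> None:
        """Drop accumulated history (keeps the current shaped proposal).

        Called mid-burn-in so the covariance estimate comes from the
        better-mixed half of the adaptation phase, not the transient."""
        self._mean = np.zeros(self.dim)
        if self.shape_cov:
            self._m2 = np.zeros((self.dim, self.dim))
        self._count = 0

    def rate(self) -> float:
        return self.accepted / self.proposed if self.proposed else np.nan


def _phi_blocks(spec: ModelSpec, block_size: int) -> list[np.ndarray]:
    """Partition kept spline cells into contiguous super-cell blocks."""
    basis = spec.basis
    kept = np.flatnonzero(basis.kept_mask)
    i, j = basis.cell_of(kept)
    key = ((i - 1) // block_size) * 10**6 + (j - 1) // block_size
    return [np.flatnonzero(key == k) for k in np.unique(key)]


def _component_project(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Remove the mean within each connected component."""
    out = x.copy()
    for comp in np.unique(labels):
        sel = labels == comp
        out[sel] -= out[sel].mean()
    return out


def run_sampler(spec: ModelSpec, config: SamplerConfig) -> Chain:
    """Sample the posterior; identical spec/config/seed gives an identical
    chain."""
    rng = np.random.default_rng(config.seed)
    state = spec.initial_state()
    lp = log_posterior_safe(state, spec)
    if not np.isfinite(lp):
        raise RuntimeError(
            "log posterior is not finite at the initial state; "
            "re-initialize (check counts and covariate scaling)")

    tm, ts = config.target_accept_multi, config.target_accept_scalar
    s0 = config.initial_scale
    blocks: dict[str, _Block] = {}

    def add(name, dim, scale, target, shape_cov=False):
        blocks[name] = _Block(name, dim, scale, target, shape_cov)

    # the alpha block carries the global wetland slope b when the SVC term
    # is on; phi~ (sum-to-zero remainder) is updated in spatial sub-blocks
    with_b = spec.include_svc and spec.Q > 0
    dim_alpha = spec.P + (1 if with_b else 0)
    add("alpha", dim_alpha, s0 / np.sqrt(dim_alpha),
        tm if dim_alpha > 1 else ts, shape_cov=True)
    phi_groups: list[np.ndarray] = []
    if with_b and spec.Q > 1:
        phi_groups = _phi_blocks(spec, config.phi_block_size)
        for g, idx in enumerate(phi_groups):
            add(f"phi_block_{g}", len(idx), s0 / np.sqrt(len(idx)),
                tm if len(idx) > 1 else ts, shape_cov=True)
    if spec.include_random_effects and spec.R > 1:
        psi_labels = spec.region_car.component_labels
        add("psi", spec.R, s0 / np.sqrt(spec.R), tm if spec.R > 2 else ts,
            shape_cov=True)
    else:
        psi_labels = None
    add("sigma2_inv", 1, 0.5, ts)
    add("tau2_inv", 1, 0.5, ts)
    # one full joint move over (alpha, phi, psi): its shaped covariance
    # learns the soft spatial-confounding directions that couple the fixed
    # effects with the coefficient surface and region effects
    dim_joint = spec.P + spec.Q + spec.R
    if spec.Q + spec.R > 0:
        add("joint", dim_joint, s0 / np.sqrt(dim_joint), tm,
            shape_cov=True)

    b_level = 0.0            # global wetland slope (phi = b + phi~)
    phi_tilde = np.zeros(spec.Q)

    names = [f"alpha_{n}" for n in spec.alpha_names]
    names += [f"phi_{q}" for q in range(spec.Q)]
    names += [f"psi_{r}" for r in range(spec.R)]
    names += ["sigma2_inv", "tau2_inv"]

    n_ret = (config.n_iterations - config.n_burnin) // config.thinning
    draws = np.empty((n_ret, len(names)))
    kept = 0

    def mh(block: _Block, proposal: ParameterState, adapting: bool,
           t: int, log_jacobian: float = 0.0) -> bool:
        """Shared Metropolis accept/reject + adaptation bookkeeping."""
        nonlocal state, lp
        lp_prop = log_posterior_safe(proposal, spec)
        acc_prob = float(np.exp(min(0.0, lp_prop - lp + log_jacobian)))
        block.proposed += 0 if adapting else 1
        accepted = rng.random() < acc_prob
        if accepted:
            state, lp = proposal, lp_prop
            block.accepted += 0 if adapting else 1
        if adapting:
            block.adapt(acc_prob, t)
        return accepted

    for t in range(config.n_iterations):
        adapting = t < config.n_burnin
        if t == config.n_burnin // 2:
            for blk in blocks.values():
                blk.reset_stats()

        b = blocks["alpha"]
        eps = b.noise(rng)
        prop = state.copy()
        prop.alpha = state.alpha + eps[: spec.P]
        if with_b:
            b_prop = b_level + eps[spec.P]
            prop.phi = b_prop + phi_tilde
        if mh(b, prop, adapting, t) and with_b:
            b_level = b_prop
        if adapting:
            b.record(np.append(state.alpha, b_level) if with_b
                     else state.alpha)

        for g, idx in enumerate(phi_groups):
            b = blocks[f"phi_block_{g}"]
            step = np.zeros(spec.Q)
            step[idx] = b.noise(rng)
            step -= step.mean()          # stay in the sum-to-zero subspace
            prop = state.copy()
            prop.phi = state.phi + step
            if mh(b, prop, adapting, t):
                phi_tilde = phi_tilde + step
            if adapting:
                b.record(phi_tilde[idx])

        if psi_labels is not None:
            b = blocks["psi"]
            prop = state.copy()
            prop.psi = state.psi + _component_project(b.noise(rng),
                                                      psi_labels)
            mh(b, prop, adapting, t)
            if adapting:
                b.record(state.psi)

        if "joint" in blocks:
            b = blocks["joint"]
            if b._chol is not None:  # engages once the covariance is ready
                eps = b.noise(rng)
                prop = state.copy()
                prop.alpha = state.alpha + eps[: spec.P]
                if spec.Q:
                    prop.phi = state.phi + eps[spec.P: spec.P + spec.Q]
                if psi_labels is not None:
                    prop.psi = state.psi + _component_project(
                        eps[spec.P + spec.Q:], psi_labels)
                if mh(b, prop, adapting, t) and with_b:
                    b_level = float(state.phi.mean())
                    phi_tilde = state.phi - b_level
            if adapting:
                b.record(np.concatenate([state.alpha, state.phi,
                                         state.psi]))

        for scale_name in ("sigma2_inv", "tau2_inv"):
            b = blocks[scale_name]
            cur = getattr(state, scale_name)
            new = cur * float(np.exp(b.noise(rng)[0]))
            prop = state.copy()
            setattr(prop, scale_name, new)
            # log-normal proposal on the natural scale: Jacobian s'/s
            mh(b, prop, adapting, t,
               log_jacobian=np.log(new) - np.log(cur))

        if not adapting and (t - config.n_burnin) % config.thinning == 0 \
                and kept < n_ret:
            draws[kept] = np.concatenate([
                state.alpha, state.phi, state.psi,
                [state.sigma2_inv, state.tau2_inv]])
            kept += 1

    acceptance = {b.name: b.rate() for b in blocks.values()}
    if config.n_iterations - config.n_burnin >= 200:
        dead = [n for n, r in acceptance.items()
                if np.isfinite(r) and r == 0.0]
        if dead:
            raise RuntimeError(
                f"blocks {dead} accepted nothing after adaptation; "
                f"acceptance rates: {acceptance}")
    return Chain(draws=draws[:kept], names=names, acceptance=acceptance,
                 seed=config.seed, config=config)
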
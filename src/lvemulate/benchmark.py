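"""Simulation-study harness comparing the eight estimation procedures.

Two emulation strategies x two interpolators x two losses = eight methods.
Each method estimates the reduced parameters for every test observation and
is scored by the parameter-space MSE against the known truth; distributions
are summarized by the median and first/third quartiles (Tukey).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .inference import (
    DEFAULT_LOWRANK_K_LOSS,
    EmulatorBundle,
    OptimConfig,
    build_loss_emulator,
    build_output_emulator,
    estimate_parameters,
    multistart_minimize,
)
from .losses import LossSpec, output_covariance
from .simulator import Dataset

__all__ = [
    "MethodSpec",
    "BenchmarkResult",
    "all_methods",
    "parameter_mse",
    "tukey_summary",
    "run_method_comparison",
    "summary_table",
    "mse_long_frame",
]


@dataclass(frozen=True)
class MethodSpec:
    strategy: str  # "output" | "loss"
    interpolator: str  # "local_gp" | "lowrank_gp"
    loss: str  # "euclidean" | "mahalanobis"

    def __post_init__(self) -> None:
        if self.strategy not in ("output", "loss"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.interpolator not in ("local_gp", "lowrank_gp"):
            raise ValueError(f"unknown interpolator {self.interpolator!r}")
        if self.loss not in ("euclidean", "mahalanobis"):
            raise ValueError(f"unknown loss {self.loss!r}")

    @property
    def label(self) -> str:
        return f"{self.strategy}+{self.interpolator}+{self.loss}"


def all_methods() -> list[MethodSpec]:
    """The eight strategy x interpolator x loss combinations."""
    return [
        MethodSpec(strategy, interpolator, loss)
        for interpolator in ("lowrank_gp", "local_gp")
        for strategy in ("output", "loss")
        for loss in ("euclidean", "mahalanobis")
    ]


def parameter_mse(theta_hat, theta_true) -> float:
    """Mean over the four components of the squared estimation error."""
    theta_hat = np.asarray(theta_hat, dtype=float).reshape(-1)
    theta_true = np.asarray(theta_true, dtype=float).reshape(-1)
    if theta_hat.shape != theta_true.shape:
        raise ValueError("parameter vectors must have equal length")
    return float(np.mean((theta_hat - theta_true) ** 2))


def tukey_summary(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) under the linear-interpolation quantile convention."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("cannot summarize an empty collection")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)


@dataclass
class BenchmarkResult:
    """Per-method MSE lists plus Tukey summaries and provenance."""

    mses: dict  # MethodSpec -> np.ndarray of per-test-point MSEs (NaN on failure)
    summaries: dict  # MethodSpec -> (median, q1, q3)
    failures: list = field(default_factory=list)  # (method label, test index, reason)
    seed: int = 0
    config_hash: str = ""


def _loss_spec_for(kind: str, train: Dataset) -> LossSpec:
    if kind == "euclidean":
        return LossSpec(kind="euclidean")
    return LossSpec(kind="mahalanobis", Sigma=output_covariance(train.outputs))


def run_method_comparison(
    train: Dataset,
    test: Dataset,
    methods: Optional[Sequence[MethodSpec]] = None,
    optim_config: OptimConfig = OptimConfig(),
    seed: int = 0,
    gp_options: Optional[dict] = None,
) -> BenchmarkResult:
    """Estimate every test point with every method and collect parameter MSEs.

    Output-strategy emulators are fitted once per (interpolator) and reused
    across test points and losses; loss-strategy emulators are refitted per
    observation, as the strategy requires.  Individual failures are recorded
    (NaN in the distribution) rather than aborting the run.
    """
    if methods is None:
        methods = all_methods()
    deduped: list[MethodSpec] = []
    for m in methods:
        if m in deduped:
            warnings.warn(f"duplicate method {m.label} removed", stacklevel=2)
        else:
            deduped.append(m)
    methods = deduped

    payload = {
        "n_train": train.n,
        "n_test": test.n,
        "methods": [m.label for m in methods],
        "seed": seed,
        "optim": vars(optim_config) | {"bounds": list(optim_config.bounds)},
    }
    config_hash = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    opt = OptimConfig(
        bounds=optim_config.bounds,
        n_starts=optim_config.n_starts,
        maxiter=optim_config.maxiter,
        tol=optim_config.tol,
        seed=seed,
    )

    # Cache heavyweight shared state across methods.
    output_bundles: dict[str, EmulatorBundle] = {}
    lowrank_loss_emulator = None
    mses = {m: np.full(test.n, np.nan) for m in methods}
    failures = []

    for m in methods:
        spec = _loss_spec_for(m.loss, train)
        if m.strategy == "output":
            if m.interpolator not in output_bundles:
                output_bundles[m.interpolator] = build_output_emulator(
                    train, m.interpolator, gp_options=gp_options
                )
            base_bundle = output_bundles[m.interpolator]
        for i in range(test.n):
            y0 = test.outputs[i]
            try:
                if m.strategy == "output":
                    bundle = EmulatorBundle(
                        strategy="output",
                        interpolator=m.interpolator,
                        emulator=base_bundle.emulator,
                        loss_spec=spec,
                        dataset=train,
                        n_outputs=train.outputs.shape[1],
                    )
                    result = estimate_parameters(
                        y0,
                        train,
                        strategy="output",
                        interpolator=m.interpolator,
                        optim_config=opt,
                        uq=False,
                        bundle=bundle,
                    )
                else:
                    if m.interpolator == "lowrank_gp":
                        b = build_loss_emulator(
                            train,
                            y0,
                            spec,
                            "lowrank_gp",
                            gp_options=gp_options,
                            reuse_emulator=lowrank_loss_emulator,
                        )
                        lowrank_loss_emulator = b.emulator

                        def objective(theta, _b=b):
                            return float(_b.emulator.predict_mean(theta))

                        theta_hat, loss_min, diag = multistart_minimize(objective, opt)
                        from .inference import InferenceResult

                        result = InferenceResult(
                            theta_hat=theta_hat,
                            loss_min=loss_min,
                            n_starts_converged=diag["n_converged"],
                            diagnostics=diag,
                        )
                    else:
                        result = estimate_parameters(
                            y0,
                            train,
                            strategy="loss",
                            interpolator=m.interpolator,
                            loss_spec=spec,
                            optim_config=opt,
                            uq=False,
                            gp_options=gp_options,
                        )
                mses[m][i] = parameter_mse(result.theta_hat, test.design[i])
                if result.n_starts_converged == 0:
                    failures.append((m.label, i, "no start converged (estimate retained)"))
            except Exception as exc:  # record, keep going
                failures.append((m.label, i, repr(exc)))

    summaries = {m: tukey_summary(mses[m][np.isfinite(mses[m])]) for m in methods}
    return BenchmarkResult(
        mses=mses, summaries=summaries, failures=failures, seed=seed, config_hash=config_hash
    )


def summary_table(result: BenchmarkResult) -> pd.DataFrame:
    """Four-row summary (interpolator x strategy) with one column per loss."""
    rows = {}
    for m, (med, q1, q3) in result.summaries.items():
        key = (m.interpolator, m.strategy)
        rows.setdefault(key, {})[m.loss] = f"{med:.4f} ({q1:.4f}, {q3:.4f})"
    frame = pd.DataFrame(
        [
            {
                "interpolation": interp,
                "emulation": strat,
                "euclidean": vals.get("euclidean", ""),
                "mahalanobis": vals.get("mahalanobis", ""),
            }
            for (interp, strat), vals in rows.items()
        ]
    )
    return frame


def mse_long_frame(result: BenchmarkResult) -> pd.DataFrame:
    """Long-form (method, test_id, mse) table, boxplot-ready."""
    records = [
        {"method": m.label, "test_id": i, "mse": float(v)}
        for m, values in result.mses.items()
        for i, v in enumerate(values)
    ]
    return pd.DataFrame(records)
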
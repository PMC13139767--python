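"""Shared helpers for building minimal fitted-model stand-ins in tests."""

import numpy as np

from telodyn.gamma_models import FitResult, ModelSpec


def fake_fit(terms=(), beta=(0.0,), var=(0.01,), loglik=-50.0, n=100):
    """A FitResult with prescribed coefficients/variances/loglik; k follows
    the usual fixed + shape accounting so AICc deltas are controlled by
    loglik alone when k is equal."""
    beta = np.asarray(beta, float)
    return FitResult(
        spec=ModelSpec(fixed_terms=tuple(terms)),
        names=["intercept"] + list(terms),
        beta=beta,
        vcov=np.diag(np.asarray(var, float)),
        shape=5.0,
        sigma_group=0.0,
        loglik=loglik,
        n=n,
        k=len(beta) + 1,
        converged=True,
        y=np.ones(n),
        mu=np.ones(n),
    )
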
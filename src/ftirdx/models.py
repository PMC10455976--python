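"""Factory for the three classification models: PCA-QDA, SPA-QDA, GA-QDA.

Each model is an sklearn Pipeline with a dimension-reduction or variable-
selection front-end followed by :class:`~ftirdx.qda.ShrinkageQDA`, so the
front-end is refitted whenever the model is refitted (e.g. inside every
Monte Carlo cross-validation iteration).
"""

from __future__ import annotations

from sklearn.pipeline import Pipeline

from .qda import CappedVariancePCA, ShrinkageQDA
from .selection import GAConfig, GASelector, SPASelector

MODEL_NAMES = ("pca-qda", "spa-qda", "ga-qda")


def build_model(
    name: str,
    *,
    variance_target: float = 0.935,
    max_components: int | None = 6,
    n_components: int | None = 6,
    spa_max_vars: int = 6,
    ga_config: GAConfig | None = None,
    covariance_mode: str = "pooled",
    val_fraction: float = 0.3,
    priors="empirical",
    shrinkage: float = 0.5,
    random_state: int = 0,
) -> Pipeline:
    """Build one of the three named models as an sklearn Pipeline."""
    qda = ShrinkageQDA(priors=priors, shrinkage=shrinkage)
    if name == "pca-qda":
        head = ("pca", CappedVariancePCA(variance_target=variance_target,
                                         max_components=max_components,
                                         n_components=n_components))
    elif name == "spa-qda":
        head = ("select", SPASelector(max_vars=spa_max_vars,
                                      covariance_mode=covariance_mode,
                                      val_fraction=val_fraction,
                                      random_state=random_state))
    elif name == "ga-qda":
        head = ("select", GASelector(config=ga_config,
                                     covariance_mode=covariance_mode,
                                     val_fraction=val_fraction,
                                     random_state=random_state))
    else:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    return Pipeline([head, ("qda", qda)])
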
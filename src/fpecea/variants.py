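"""Structural model variants.

Variant I adds nursing-home admissions for reasons other than a hip
fracture: the WELL and POST_FRACTURE rows gain a transition into
NURSING_HOME, composed before the residual self-loop.

Variant II adds an acute vertebral-fracture tunnel state and a
post-vertebral state; the outcome measure becomes combined hip + vertebral
fractures avoided, and vertebral events carry their own treatment and care
costs.

The additional transition probabilities and costs are user-supplied through
the same CSV schema as the base tables (the published model reports them
only in supplementary material); the bundled ``*_synthetic.csv`` examples
are constructed stand-ins for demonstration and qualitative testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .parameters import ParameterSet

__all__ = ["VariantConfig", "VariantConfigurationError", "apply_variant",
           "example_variant_table"]

VARIANT_CLINICAL = {
    "I": ("p_nh_other_well", "p_nh_other_post"),
    "II": ("p_vert_fracture", "p_vert_refracture",
           "p_mort_vert_acute", "p_mort_vert_post"),
}
VARIANT_COSTS = {"I": (), "II": ("vert_treatment_cost", "ltc_vert_post")}


class VariantConfigurationError(ValueError):
    """A structural variant was requested without its required parameters."""


@dataclass
class VariantConfig:
    """Which variant to activate and where its extra parameters come from.

    ``table`` may be a DataFrame in the standard parameter schema or a path
    to such a CSV; rows are split into probabilities and costs by parameter
    name.
    """

    id: str
    table: pd.DataFrame | str | Path

    def __post_init__(self):
        if self.id not in ("I", "II"):
            raise VariantConfigurationError(
                f"unknown variant {self.id!r}; expected 'I' or 'II'"
            )

    def frame(self) -> pd.DataFrame:
        if isinstance(self.table, pd.DataFrame):
            return self.table.copy()
        return pd.read_csv(self.table)


def apply_variant(params: ParameterSet, cfg: VariantConfig) -> ParameterSet:
    """Return a ParameterSet with the variant's extra rows merged in.

    The result carries a ``variant`` marker that extends the engine's state
    space (variant II) and transition wiring.  Raises
    :class:`VariantConfigurationError` listing any missing parameters.
    """
    frame = cfg.frame()
    present = set(frame["parameter"])
    needed = set(VARIANT_CLINICAL[cfg.id]) | set(VARIANT_COSTS[cfg.id])
    missing = sorted(needed - present)
    if missing:
        raise VariantConfigurationError(
            f"variant {cfg.id} requires parameters: {missing}"
        )
    clin_rows = frame[frame["parameter"].isin(VARIANT_CLINICAL[cfg.id])]
    cost_rows = frame[frame["parameter"].isin(VARIANT_COSTS[cfg.id])]

    ps = params.copy()
    clinical = pd.concat(
        [ps.clinical, clin_rows[ps.clinical.columns.intersection(clin_rows.columns)]],
        ignore_index=True,
    )
    if not cost_rows.empty:
        costs = pd.concat(
            [ps.costs, cost_rows[ps.costs.columns.intersection(cost_rows.columns)]],
            ignore_index=True,
        )
    else:
        costs = ps.costs
    out = ParameterSet(
        clinical=clinical, costs=costs, intervention=ps.intervention,
        effect=ps.effect, settings=ps.settings, variant={"id": cfg.id},
    )
    return out


def example_variant_table(variant_id: str) -> pd.DataFrame:
    """The bundled synthetic example parameters for a variant."""
    import importlib.resources

    root = importlib.resources.files("fpecea") / "data" / "variants"
    name = f"variant_{variant_id}_synthetic.csv"
    return pd.read_csv(str(root / name))
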
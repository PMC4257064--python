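"""End-to-end synthetic pipeline: simulate, detect, model, project, validate.

Mirrors the study design on a synthetic landscape: clearing is simulated
over a fitting epoch (default 6 years) and a validation epoch (default 3
years, with the prior-deforestation distance updated in between so change
keeps following past change); three noisy classifiers observe each epoch;
their consensus supplies presences for the risk model; the model fitted on
the first epoch is validated against the second; and the realized rate
drives the hard projection and carbon numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import synthetic
from .consensus import ChangeLayer, consensus, sample_background, sample_presence
from .evaluate import ValidationReport, evaluate
from .grid import Grid, LandscapeStack, area_ha, distance_transform
from .maxent import MaxentResults, MaxentRiskModel
from .projection import HardMap, carbon_at_risk, harden
from .rates import CarbonParams, RatePeriod, project_forest

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything a full synthetic run produces."""

    stack: LandscapeStack
    truth_fit: Grid  # true forest at fit-epoch end
    truth_val: Grid  # true forest at validation-epoch end
    change_fit: ChangeLayer
    change_val: ChangeLayer
    model: MaxentRiskModel
    results: MaxentResults
    risk: Grid
    rate_fit: RatePeriod
    rate_val: RatePeriod
    hard: HardMap | None
    carbon: tuple[float, float] | None
    validation: ValidationReport | None
    presence: np.ndarray = field(repr=False, default=None)
    background: np.ndarray = field(repr=False, default=None)


def _observe(truth_start: Grid, truth_end: Grid, config: synthetic.SimConfig,
             epoch_tag: int) -> list[tuple[Grid, Grid]]:
    """Three classifier (start, end) pairs for one epoch."""
    cfg = synthetic.SimConfig(**{**config.to_dict(),
                                 "seed": config.seed + 1_000_003 * epoch_tag})
    starts = synthetic.emit_classifications(truth_start, cfg)
    cfg_end = synthetic.SimConfig(**{**config.to_dict(),
                                     "seed": config.seed + 1_000_003 * epoch_tag + 17})
    ends = synthetic.emit_classifications(truth_end, cfg_end)
    return list(zip(starts, ends))


def run_pipeline(config: synthetic.SimConfig | None = None, seed: int = 0,
                 fit_years: float = 6.0, val_years: float = 3.0,
                 n_presence: int = 500, n_background: int = 5000,
                 variables: tuple[str, ...] = ("accessibility", "land_designation"),
                 project_years: float = 11.0,
                 carbon_params: CarbonParams | None = None,
                 n_nochange: int = 500,
                 evaluate_map: bool = True) -> PipelineResult:
    """Run simulate -> consensus -> fit -> predict -> harden -> validate.

    ``seed`` drives every stochastic step; the same seed reproduces the
    whole run bit-identically.  ``n_presence`` is capped at the available
    consensus-deforested cells.
    """
    if config is None:
        config = synthetic.SimConfig(seed=seed)
    else:
        config = synthetic.SimConfig(**{**config.to_dict(), "seed": seed})

    stack = synthetic.generate_landscape(config)
    forest0 = stack.forest[0]

    truth_fit = synthetic.simulate_deforestation(stack, config, epoch=1, years=fit_years)
    stack.add_forest(1, truth_fit)
    # change begets change: update the prior-deforestation distance
    prior2 = np.asarray(stack["prior_deforestation"].values, bool) | (
        np.asarray(forest0.values, bool) & ~np.asarray(truth_fit.values, bool)
    )
    stack.variables["distance_to_prior_deforestation"] = distance_transform(
        forest0.copy_with(values=prior2)
    )
    truth_val = synthetic.simulate_deforestation(stack, config, epoch=2, years=val_years)
    stack.add_forest(2, truth_val)

    change_fit = consensus(_observe(forest0, truth_fit, config, 1))
    change_val = consensus(_observe(truth_fit, truth_val, config, 2))

    n_def = int(np.asarray(change_fit.deforested_mask.values, bool).sum())
    presence = sample_presence(change_fit, n=min(n_presence, n_def), seed=seed + 11)
    n_cells = int((~stack.nodata_mask).sum())
    background = sample_background(stack, n=min(n_background, n_cells), seed=seed + 13)

    model = MaxentRiskModel.from_stack(stack, presence, background, list(variables))
    results = model.fit()
    risk = results.predict(stack)

    t_mid, t_end = fit_years, fit_years + val_years
    rate_fit = RatePeriod(0.0, t_mid, area_ha(forest0), area_ha(truth_fit))
    rate_val = RatePeriod(t_mid, t_end, area_ha(truth_fit), area_ha(truth_val))

    A0 = area_ha(truth_val)
    _, loss = project_forest(A0, rate_val.r, project_years)
    hard = carbon = None
    if 0 <= loss <= A0:
        hard = harden(risk, truth_val, loss)
        carbon = carbon_at_risk(hard, carbon_params or CarbonParams())

    validation = None
    if evaluate_map:
        validation = evaluate(risk, change_val, stack, n_nochange=n_nochange,
                              seed=seed + 17)

    return PipelineResult(
        stack=stack, truth_fit=truth_fit, truth_val=truth_val,
        change_fit=change_fit, change_val=change_val, model=model,
        results=results, risk=risk, rate_fit=rate_fit, rate_val=rate_val,
        hard=hard, carbon=carbon, validation=validation,
        presence=presence, background=background,
    )
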
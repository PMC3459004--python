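import numpy as np
import pytest

from dyadscan import glm
from dyadscan import synthetic as syn


@pytest.fixture(scope="session")
def small_cfg():
    return syn.SimulationConfig(shape=(8, 8, 6))


@pytest.fixture(scope="session")
def fitted_subject(small_cfg):
    """One subject's six simulated runs fitted with the standard model.

    Study-condition bookkeeping (TR 3 s, 85 volumes/run, 5 discarded, six
    runs) on a small grid; shared by several tests to keep the suite fast.
    """
    cfg = small_cfg
    run_types = ["concordant", "discordant"] * 3
    runs, events, schedules = [], [], []
    for i, rt in enumerate(run_types):
        sched = syn.simulate_task_schedule(cfg, rt, seed=100 + i)
        bold, _ = syn.simulate_dyad_bold(sched, sched, cfg, paired=False, seed=200 + i)
        runs.append(bold.drop_leading(cfg.discard_leading))
        events.append(sched.event_tables()[0])
        schedules.append(sched)
    design = glm.design_for_runs(events, cfg.tr, runs[0].n_volumes)
    data = np.concatenate([r.timeseries() for r in runs], axis=0)
    result = glm.fit_glm(data, design)
    return {
        "cfg": cfg,
        "runs": runs,
        "events": events,
        "schedules": schedules,
        "design": design,
        "result": result,
        "rois": cfg.roi_masks(),
    }
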
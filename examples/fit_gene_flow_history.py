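"""Estimate a gene-flow chronology from one simulated population pair.

The full pipeline in miniature: simulate an observed joint SFS under the
stepwise-declining gene-flow scenario, fit the two-epoch IM model at a
small grid of epoch boundaries X (the fit at each X estimates t2, the
gene-flow rate integrated from the present to X), then smooth and
deconvolve t2 into per-interval rates.  Runs a few minutes on one core.
"""

import numpy as np

from gfchrono.deconv import T2Trajectory, deconvolve_intervals, smooth_t2
from gfchrono.im_fit import default_x_grid, scan_gene_flow
from gfchrono.synthetic import schedule_from_model
from gfchrono.validation import MINI_SAMPLES, mini_scenario, search_config
from gfchrono.coalescent import simulate_observed_sfs

mini = mini_scenario(5)
obs = simulate_observed_sfs(mini, MINI_SAMPLES, seed=11, fold=True)
grid = default_x_grid(100, 900, 100)

scan = scan_gene_flow(obs, grid,
                      search_config(mini, "full", seed=2),
                      warm_cfg=search_config(mini, "track", seed=2))
traj = T2Trajectory.from_scan(scan)
res = deconvolve_intervals(smooth_t2(traj, lam=1e12), x=grid)

true_act = schedule_from_model(mini.model, grid)
print("interval (gen)   est. rate    true rate")
for x, est, tru in zip(grid, res.act_raw, true_act):
    print(f"{x - 100:5.0f}-{x:5.0f}      {est:9.3g}   {tru:9.3g}")
print()
print(f"recent third mean {res.act_raw[:3].mean():.3g}  vs  "
      f"old third mean {res.act_raw[-3:].mean():.3g}")
print("The generating schedule shuts gene flow down toward the present;")
print("a recovered recent-below-old contrast is the qualitative signal")
print("the estimator is validated on.")
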
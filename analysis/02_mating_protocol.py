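#!/usr/bin/env python
"""Validate the exhaustive-mating interpolation estimator.

Checks the 2x(flanking 1-day vials) rule for uncounted 4-day blocks: exact
under linear daily decline, and its relative error under geometric decline.
Then applies the estimator to a simulated population's vial series and
reports the agreement with true totals.
"""

import json
import sys
from pathlib import Path

import numpy as np

import drivemap as dm
from drivemap.protocol import vial_series_from_daily

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    report = {}

    daily = [(100 - 5 * d, 0) for d in range(1, 14)]
    truth = sum(f for f, _ in daily)
    est = dm.interpolate_total(vial_series_from_daily(daily)).total
    report["linear_decay"] = {"true_total": truth, "estimate": est, "error": est - truth}
    print(f"linear decline: true {truth}, interpolated {est} (error {est - truth:+g})")

    geo = {}
    for rate in (0.85, 0.90, 0.95):
        daily = [(round(150 * rate ** (d - 1)), 0) for d in range(1, 19)]
        truth = sum(f for f, _ in daily)
        est = dm.interpolate_total(vial_series_from_daily(daily)).total
        geo[rate] = {"true_total": truth, "estimate": est, "rel_error": (est - truth) / truth}
        print(f"geometric (rate {rate}): true {truth}, interpolated {est:.0f} "
              f"({(est - truth) / truth:+.2%})")
    report["geometric_decay"] = geo

    gmap = dm.build_study_map("Exp2")
    model = dm.default_effect_model()
    genos = dm.simulate_mapping_population(
        dm.study_design("Exp2", 200), gmap, dm.stage_seed(SEED, "genotypes")
    )
    phen = dm.simulate_phenotypes(genos, model, gmap, dm.stage_seed(SEED, "phenotypes"))
    rng = np.random.default_rng(dm.stage_seed(SEED, "vials"))
    errs = []
    for p in phen:
        if p.T == 0:
            continue
        series = dm.simulate_vial_series(p, rng=rng)
        errs.append(dm.interpolate_total(series).total - p.T)
    errs = np.array(errs)
    report["population"] = {
        "n_fertile": len(errs),
        "mean_error": float(errs.mean()),
        "mean_abs_rel_error": float(np.mean(np.abs(errs)) / np.mean([p.T for p in phen if p.T > 0])),
    }
    print(f"population of {len(errs)} fertile males: mean interpolation error "
          f"{errs.mean():+.2f} offspring")
    (OUT / "protocol_validation.json").write_text(json.dumps(report, indent=1))
    print(f"wrote {OUT}/protocol_validation.json")


if __name__ == "__main__":
    main()
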
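#!/usr/bin/env python
"""Value-of-information analysis: EVPI and grouped EVPPI.

Values perfect information for the NephroCheck versus standard-care
comparison at £20,000/QALY, scaled to the annual national AKI caseload
over a ten-year horizon, and ranks parameters/groups by EVPPI.  Also
reports the published per-patient EVPI scaled to the population as an
arithmetic cross-check of the scaling convention.
"""

from pathlib import Path

from akicea.pipeline import default_config, run_psa, run_voi
from akicea.voi import population_evpi

OUT = Path(__file__).resolve().parent.parent / "results"
SEED, DRAWS = 42, 1000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = default_config(seed=0)
    results = run_psa(config, n_draws=DRAWS, seed=SEED)
    vr = run_voi(results, config)
    vr.evppi.to_csv(OUT / "evppi_ranking.csv", index=False)

    print(f"EVPI (fixture, {DRAWS} draws): £{vr.evpi_per_patient:.2f} per patient, "
          f"£{vr.population_evpi / 1e6:.1f}M population over 10 years")
    print("\ntop EVPPI subsets:")
    print(vr.evppi.head(8).to_string(index=False))

    check = population_evpi(11.62, 564_738, 10)
    print(f"\nscaling check: £11.62/patient x 564,738/yr x 10 yr = £{check / 1e6:.1f}M")


if __name__ == "__main__":
    main()
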
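"""Generate a small synthetic multi-site validation study on disk.

Simulates two EDs for a week — nonhomogeneous Poisson arrivals on a
diurnal curve, lognormal stays, load-dependent physician delays — plus
staff workload ratings at the five daily assessment clock times, and
writes visits.csv / assessments.csv / sites.yaml / grid.yaml / truth.json
to ./example_study. Everything is reproducible from the seed.
"""

from edload.simulate import DEFAULT_SITES, SimConfig, simulate_dataset
from edload.visit_log import write_assessments, write_grid, write_sites, write_visit_log
from pathlib import Path

out = Path("example_study")
out.mkdir(exist_ok=True)
config = SimConfig(seed=17, n_days=7, sites=DEFAULT_SITES[:2])
result = simulate_dataset(config)

write_visit_log(result.records, out / "visits.csv")
write_assessments(result.assessments, out / "assessments.csv")
write_sites(result.sites, out / "sites.yaml")
write_grid(result.grid, out / "grid.yaml")
(out / "truth.json").write_text(result.truth.to_json())

lat = result.truth.latent["latent"]
print(f"{len(result.records)} visits at {len(result.sites)} sites over {config.n_days} days")
print(f"{len(result.assessments)} workload ratings at {len(result.grid)} timepoints")
print(f"latent workload spans {lat.min():.2f}-{lat.max():.2f} on the 1-6 scale")
print(f"files written to {out}/")
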
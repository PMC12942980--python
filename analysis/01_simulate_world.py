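"""Generate the synthetic study system and write its raw tables.

Produces the "observed" (corrupted) occurrence table, the ground-truth
defect labels, the country polygons and the species biting-frequency
table under results/world/.
"""

import argparse
from pathlib import Path

import numpy as np

from tickclim import synthetic


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/world"))
    args = ap.parse_args()

    world = synthetic.make_world(seed=args.seed)
    synthetic.write_world(world, args.outdir)

    occ = world.occurrences
    base = world.climate[world.slices[0]]
    t = base["monthly_temp"].values
    print(f"world seed={args.seed}: {len(occ)} occurrence rows "
          f"({len(world.clean_occurrences)} genuine + "
          f"{len(world.truth)} injected defects)")
    print(f"  genera: {sorted(occ['genus'].unique())}")
    print(f"  defects: {world.truth['defect'].value_counts().to_dict()}")
    print(f"  slices: {world.slices}, monthly T range "
          f"[{np.nanmin(t):.1f}, {np.nanmax(t):.1f}] degC at baseline")
    print(f"  countries: {len(world.countries)}, population total "
          f"{np.nansum(world.population[world.slices[0]].values):.3g}")
    print(f"written to {args.outdir}/")


if __name__ == "__main__":
    main()
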
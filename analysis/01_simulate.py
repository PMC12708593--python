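"""Simulate the study system: a 500 m x 300 m stem-mapped plot with two
censuses a decade apart, terrain, rock bareness, and a sapling layer.

Writes census and environment tables under results/data/.
"""

from _common import SEED, DATA, generate, save_inputs


def main():
    cfg, cen_a, cen_b, corner_z, rbr, saplings = generate(SEED)
    save_inputs(cfg, cen_a, cen_b, corner_z, rbr, saplings)
    n_adult_a = len(cen_a.adults())
    n_adult_b = len(cen_b.adults())
    print(f"seed {SEED}: plot {cfg.width:.0f} x {cfg.height:.0f} m")
    print(f"census 2011: {cen_a.n} stems ({n_adult_a} adults >= {cfg.dbh_threshold} cm)")
    print(f"census 2021: {cen_b.n} stems ({n_adult_b} adults)")
    print(f"terrain: {corner_z.min():.0f}-{corner_z.max():.0f} m elevation; "
          f"{len(saplings)} sapling abundance rows")
    print(f"written to {DATA}")


if __name__ == "__main__":
    main()
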
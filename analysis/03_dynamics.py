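"""Individual-level dynamics 2011 -> 2021: fate classification and the
flow distributions of each structure index for survivors, dead trees
and recruits, plus Sankey link data.
"""

import json

from _common import RESULTS, adults, load_inputs
from standstruct.census import pair_censuses
from standstruct.dynamics import classify_fates, flow_table, sankey_links
from standstruct.structure import PARAM_NAMES, compute_structure


def main():
    _, cen_a, cen_b, *_ = load_inputs()
    out = RESULTS / "dynamics"
    out.mkdir(parents=True, exist_ok=True)

    pair = pair_censuses(cen_a, cen_b)
    fates = classify_fates(pair)
    print(f"fates: {fates.counts()} "
          f"({len(fates.missing_assumed_dead)} missing adults assumed dead)")

    st_a = compute_structure(adults(cen_a))
    st_b = compute_structure(adults(cen_b))
    for process in ("survivor", "mortality", "recruitment"):
        t = flow_table(fates, st_a, st_b, process)
        t.to_csv(out / f"flows_{process}.csv", index=False)
        top = t.set_index("category")[["W_pct", "U_pct", "M_pct"]].idxmax()
        print(f"{process}: modal categories W={top['W_pct']} "
              f"U={top['U_pct']} M={top['M_pct']}")

    links = {p: sankey_links(fates, st_a, st_b, p) for p in PARAM_NAMES}
    (out / "sankey.json").write_text(json.dumps(links, indent=1))
    print(f"flow tables and sankey links written to {out}")


if __name__ == "__main__":
    main()
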
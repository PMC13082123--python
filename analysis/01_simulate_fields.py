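#!/usr/bin/env python
"""Generate the example study fields: an intact network and its
source-ablated twin.

Writes two plain-CSV datasets under results/data/ — a 10-min, 40-Hz field of
50 cells in which 10 rhythmic source cells drive 10 couplings at
physiological speeds, and the same field with the sources' drive removed
(identical layout, background events and noise draws).
"""

from pathlib import Path

from gliowave import SimConfig, simulate_field, write_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 1


def main() -> None:
    cfg = SimConfig(seed=SEED)
    for tag, ablated in (("intact", False), ("ablated", True)):
        rois, truth, traces = simulate_field(cfg, ablated=ablated)
        paths = write_dataset(rois, traces, truth, OUT / tag, cfg)
        n_events = sum(len(truth.event_times(c)) for c in truth.cell_ids)
        print(f"{tag}: {len(truth.cell_ids)} cells, "
              f"{len(truth.true_edges)} true couplings, "
              f"{n_events} calcium events -> {paths['traces'].parent}")


if __name__ == "__main__":
    main()
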
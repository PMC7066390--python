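"""Produce the published per-tile dataset folder from a synthetic tile.

Runs the whole pipeline on one generated 4-channel tile and lists the
resulting folder: 19 PNGs (originals, cartoons, segmentation masks,
convex-hull masks, double-stain masks, tissue evaluation mask) plus the
plain-text logfile, all named by the dataset convention.
"""

import tempfile
from pathlib import Path

from lymphoseg import PipelineConfig, generate_tile, process_tile


def main() -> None:
    images, _ = generate_tile(seed=1)
    cfg = PipelineConfig(threshold_step=4)  # coarser sweep for a quick demo
    with tempfile.TemporaryDirectory() as tmp:
        folder = process_tile(images, (1, 1, 1), cfg, tmp)
        files = sorted(p.name for p in folder.iterdir())
        print(f"{folder.name}: {len(files)} files")
        for name in files:
            print("   ", name)


if __name__ == "__main__":
    main()
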
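"""Build the three age-specific G6-G9 airway surfaces and export them.

Constructs the centerline trees (70 degree planar bifurcations) and the
watertight triangulated surfaces for infant, child and adult, checks the
geometric invariants (cap areas, enclosed volume, mid-section areas), and
writes STL + VTK surfaces under results/geometry/.
"""

from pathlib import Path

import numpy as np

from airwaycfd import geometry as G

OUT = Path(__file__).resolve().parents[1] / "results" / "geometry"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for age in ["infant", "child", "adult"]:
        profile = G.build_profile(age)
        tree = G.build_centerline_tree(profile)
        surface = G.build_surface(tree, profile, resolution=0.12)
        G.export_surface(surface, OUT / f"{age}.stl", "stl")
        G.export_surface(surface, OUT / f"{age}.vtk", "vtk")
        d6 = profile.generation(6).diameter_mm * 1e-3
        inlet_ratio = surface.patch_area("inlet") / (np.pi * (d6 / 2) ** 2)
        print(
            f"{age}: {len(surface.triangles)} triangles, "
            f"volume {surface.enclosed_volume * 1e9:.1f} mm^3, "
            f"inlet area within {abs(1 - inlet_ratio) * 100:.1f}% of the G6 disk"
        )


if __name__ == "__main__":
    main()
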
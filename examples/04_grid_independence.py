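"""Grid-independence check on sampled cross-section profiles.

Builds sampled pressure/velocity lines for three mesh resolutions of the
same (synthetic) solution, where the coarsest mesh is still 8% off and the
middle mesh is within 2% of the finest, and runs the 5% independence
assessment between adjacent refinement levels.
"""

import numpy as np

from echobc import SampledProfile, assess

x = np.linspace(0.0, 0.012, 40)  # 12 mm line through the stenosis


def mesh_profiles(label, error):
    """Profiles converging toward the reference as `error` shrinks."""
    shape = 2.5 * np.exp(-((x - 0.006) ** 2) / 2e-5)
    return [
        SampledProfile(
            station="stenosis_local",
            position=x,
            pressure=(1.0 + error) * (8.0 - 400.0 * x),
            velocity=(1.0 + error) * shape,
            mesh_label=label,
        )
    ]


meshes = {
    "0.5M": mesh_profiles("0.5M", 0.08),
    "2M": mesh_profiles("2M", 0.02),
    "4M": mesh_profiles("4M", 0.00),
}

report = assess(meshes, threshold=0.05)
print(report.summary())
print()
print("the 0.5M -> 2M pair exceeds 5%, the 2M -> 4M pair is within it:")
print("2M cells is the coarsest resolution giving grid-independent results,")
print("so production runs would use the ~2M-cell mesh.")
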
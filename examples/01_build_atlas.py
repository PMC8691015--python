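"""Build the six surrogate substructures from one heart contour.

A synthetic heart mesh plus two landmarks (aortic root center, truncus
pulmonalis point) fully determine the atlas: valve cone and sphere,
1 cm myocardial shell with its left/right anterior walls, and the 2 cm
inner-margin "deep structures" core.
"""

from heartatlas import AtlasParams, CohortConfig, build_structure_set, generate_heart

config = CohortConfig()
heart, landmarks = generate_heart(config, patient_index=0)
print(f"true heart volume: {heart.volume / 1000:.1f} cm^3")
print(f"aortic root at {landmarks.aortic_root_center.round(1)} mm")

structure_set = build_structure_set(
    heart, landmarks, params=AtlasParams(grid_spacing=2.0)
)
print("\nstructure volumes (cm^3):")
for name, mesh in structure_set.structures.items():
    print(f"  {name:26s} {mesh.volume / 1000:7.1f}")

# The myocardium is the 1 cm outer layer below the aortic root, so its
# volume is roughly (heart surface area) x 1 cm; the deep-structures
# core keeps what survives a 2 cm erosion of the whole heart.
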
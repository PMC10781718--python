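"""Package-wide numeric defaults.

All tolerances are module-level constants so downstream code can override
them in one place; functions also accept explicit keyword overrides.
"""

#: geometric residual tolerance (mm) for plane containment / unit normals
GEOM_TOL = 1e-9

#: default voxel pitch (mm); matches the 0.3 mm slice thickness of the
#: follow-up CBCT protocol the meshes stand in for
DEFAULT_VOXEL_PITCH = 0.3

#: fixed ray direction for the point-in-mesh parity test; slightly skewed
#: off-axis so rays never graze axis-aligned edges or vertices of
#: grid-aligned phantom geometry
RAY_DIRECTION = (1.0, 1e-3, 1e-6)

#: relative tolerance for analytic-vs-mesh volume agreement (0.5 %)
MESH_VOLUME_RTOL = 5e-3

#: relative tolerance for voxel-vs-analytic volume agreement (2 %)
VOXEL_VOLUME_RTOL = 2e-2

#: scale applied to mesh coordinates on read (STL carries no units)
UNITS_SCALE = 1.0
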
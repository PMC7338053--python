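"""Channel-role vocabulary shared by the simulator and the analyses.

Roles name what the channel reports, mirroring the marker proteins used in
live-cell yeast imaging: the regulatable fluorescent cargo, the early Golgi
marker Vrg4, the late Golgi marker Sec7, the GGA adaptor Gga2, the AP-1
subunit Apl2, the PVE (prevacuolar endosome) marker Vps8 and the vacuole
membrane marker Vph1.
"""

CARGO = "cargo"
EARLY_GOLGI = "early_golgi"
LATE_GOLGI = "late_golgi"
ADAPTOR_GGA = "adaptor_gga"
ADAPTOR_AP1 = "adaptor_ap1"
PVE = "pve"
VACUOLE_MEMBRANE = "vacuole_membrane"

#: canonical channel ordering for rendered movies
CANONICAL_ORDER = (
    CARGO,
    EARLY_GOLGI,
    LATE_GOLGI,
    ADAPTOR_GGA,
    ADAPTOR_AP1,
    PVE,
    VACUOLE_MEMBRANE,
)

#: roles rendered as filled/shell vacuole geometry rather than puncta
VACUOLE_SHELL_ROLES = frozenset({VACUOLE_MEMBRANE})
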
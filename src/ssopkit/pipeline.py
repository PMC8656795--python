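"""End-to-end orchestration: frames -> modulation -> reflectance ->
optical properties -> StO2 -> ROI table.

The demodulation route is selected from the stack itself: three phases
at the modulated frequency run classic three-phase SFDI, a single frame
runs single-snapshot (SSOP) Fourier demodulation.  Both modulation
amplitudes are taken from the modulated stack (M_DC from the frame
mean or low band, M_AC from the carrier); when a planar fx = 0 stack is
present its mean is used for M_DC instead.  Either convention cancels
in calibration because the reference stack is processed identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as sio
from .calibration import ReflectanceMaps, reflectance_from_modulation
from .chromophores import (
    StO2Map,
    concentrations_from_mua,
    load_extinction_table,
    sto2 as compute_sto2,
)
from .demodulation import (
    THREE_PHASES,
    FrameStack,
    ModulationMaps,
    SSOPFilterConfig,
    demodulate_ssop,
    demodulate_three_phase,
    fx_to_cycles_per_pixel,
)
from .forward_model import (
    LUT,
    OpticalProperties,
    OpticalPropertyMaps,
    build_lut,
    invert_optical_properties,
)
from .roi_analysis import extract_roi_means

__all__ = ["AcquisitionConfig", "PipelineResult", "process_acquisition", "demodulate_stack"]

#: QC bit set in the StO2 map where the upstream LUT inversion was clamped.
QC_UPSTREAM_OUT_OF_LUT = 8


@dataclass
class AcquisitionConfig:
    """Acquisition geometry, reference phantom and processing options."""

    wavelengths: tuple = (665.0, 860.0)
    fx_dc: float = 0.0
    fx_ac: float = 0.2
    phases: tuple = THREE_PHASES
    pixel_pitch: float = 0.5
    n: float = 1.4
    reference_op: dict = field(default_factory=dict)  # wavelength -> OpticalProperties
    lut_mu_a_grid: np.ndarray | None = None
    lut_mu_s_grid: np.ndarray | None = None
    ssop_filter: SSOPFilterConfig = field(default_factory=SSOPFilterConfig)

    def __post_init__(self):
        if not self.fx_ac > self.fx_dc >= 0:
            raise ValueError("require fx_ac > fx_dc >= 0")
        if len(self.phases) not in (1, 3):
            raise ValueError("phases must have 1 (SSOP) or 3 (SFDI) entries")
        ref = {}
        for k, v in self.reference_op.items():
            if isinstance(v, dict):
                v = OpticalProperties(**v)
            ref[float(k)] = v
        self.reference_op = ref

    def reference_for(self, wavelength: float) -> OpticalProperties:
        if float(wavelength) in self.reference_op:
            return self.reference_op[float(wavelength)]
        if not self.reference_op:
            # default tissue-like calibration standard
            return OpticalProperties(mu_a=0.01, mu_s_prime=1.0, n=self.n)
        raise KeyError(f"no reference phantom properties for {wavelength} nm")

    @classmethod
    def from_yaml(cls, path) -> "AcquisitionConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "ssop_filter" in raw:
            raw["ssop_filter"] = SSOPFilterConfig(**raw["ssop_filter"])
        for key in ("wavelengths", "phases"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def content_hash(self) -> str:
        payload = {
            "wavelengths": list(self.wavelengths),
            "fx_dc": self.fx_dc,
            "fx_ac": self.fx_ac,
            "phases": list(self.phases),
            "pixel_pitch": self.pixel_pitch,
            "n": self.n,
            "reference_op": {
                str(k): [v.mu_a, v.mu_s_prime, v.n] for k, v in self.reference_op.items()
            },
            "ssop_filter": [
                self.ssop_filter.split_frac,
                self.ssop_filter.transition_frac,
                self.ssop_filter.margin_factor,
            ],
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    modulation: dict  # wavelength -> ModulationMaps (sample)
    reflectance: dict  # wavelength -> ReflectanceMaps
    optical_properties: dict  # wavelength -> OpticalPropertyMaps
    sto2_map: StO2Map
    roi_table: object | None
    method: str
    edge_margin: int
    qc_summary: dict
    run_log: dict


def demodulate_stack(stack: FrameStack, config: AcquisitionConfig) -> ModulationMaps:
    """Route a frame stack to three-phase or SSOP demodulation.

    Three frames at the modulated frequency -> three-phase; one frame ->
    SSOP.  If the stack also carries planar (fx = 0) frames, their mean
    replaces the modulated stack's M_DC estimate (and is halved to stay
    on the same amplitude convention).
    """
    ac = stack.select(config.fx_ac)
    if len(ac.frames) == 3:
        order = np.argsort(ac.phase)
        i1, i2, i3 = ac.frames[order]
        maps = demodulate_three_phase(i1, i2, i3, fx_ac=config.fx_ac)
    elif len(ac.frames) == 1:
        k0 = fx_to_cycles_per_pixel(config.fx_ac, stack.pixel_pitch)
        maps = demodulate_ssop(
            ac.frames[0], k0, config.ssop_filter, modulation_axis=stack.modulation_axis
        )
        maps.fx_ac = config.fx_ac
    else:
        raise ValueError(
            f"expected 1 (SSOP) or 3 (SFDI) frames at fx={config.fx_ac}, "
            f"got {len(ac.frames)}"
        )
    try:
        planar = stack.select(0.0)
    except ValueError:
        planar = None
    if planar is not None and config.fx_ac != 0.0:
        # planar frames measure gain * R_d(0); halve to match the
        # modulated-stack convention M_DC = gain * R_d(0) / 2
        maps.m_dc = planar.frames.mean(axis=0) / 2.0
    return maps


def process_acquisition(
    config: AcquisitionConfig,
    sample_stacks: dict,
    reference_stacks: dict,
    roi_masks: dict | None = None,
    luts: dict | None = None,
    extinction=None,
    output_dir=None,
    subject: str = "s1",
) -> PipelineResult:
    """Run the full workflow on one acquisition.

    Per wavelength: demodulate sample and reference, calibrate to
    diffuse reflectance, invert optical properties through the LUT;
    then unmix absorption at the two wavelengths into hemoglobin
    concentrations and StO2, and (when masks are given) extract ROI
    means.  Intermediates are persisted under ``output_dir`` when
    provided; the run log records the config hash.
    """
    wavelengths = tuple(float(w) for w in config.wavelengths)
    if len(wavelengths) != 2:
        raise ValueError("StO2 unmixing requires exactly two wavelengths")
    extinction = extinction or load_extinction_table()

    modulation: dict = {}
    reflectance: dict = {}
    op_maps: dict = {}
    method = None
    margin = 0
    for w in wavelengths:
        stage = f"demodulation[{w}nm]"
        try:
            if w not in sample_stacks:
                raise KeyError(f"no sample stack for {w} nm")
            m_sample = demodulate_stack(sample_stacks[w], config)
            m_ref = demodulate_stack(reference_stacks[w], config)
        except Exception as exc:
            raise RuntimeError(f"{stage}: {exc}") from exc
        if method is None:
            method = m_sample.method
        margin = max(margin, m_sample.edge_margin, m_ref.edge_margin)
        modulation[w] = m_sample

        stage = f"calibration[{w}nm]"
        try:
            refl = reflectance_from_modulation(
                m_sample, m_ref, config.reference_for(w),
                (config.fx_dc, config.fx_ac), w,
            )
        except Exception as exc:
            raise RuntimeError(f"{stage}: {exc}") from exc
        reflectance[w] = refl

        stage = f"inversion[{w}nm]"
        try:
            if luts and w in luts:
                lut = luts[w]
            else:
                lut = build_lut(
                    config.lut_mu_a_grid, config.lut_mu_s_grid,
                    config.fx_dc, config.fx_ac, config.n,
                )
            rd_dc = np.where(refl.mask, refl.rd_dc, np.nan)
            rd_ac = np.where(refl.mask, refl.rd_ac, np.nan)
            ops = invert_optical_properties(rd_dc, rd_ac, lut)
            ops.wavelength = w
        except Exception as exc:
            raise RuntimeError(f"{stage}: {exc}") from exc
        op_maps[w] = ops

    stage = "chromophores"
    try:
        w1, w2 = wavelengths
        c_hbo2, c_hb = concentrations_from_mua(
            op_maps[w1].mu_a, op_maps[w2].mu_a, extinction, (w1, w2)
        )
        sto2_map = compute_sto2(c_hbo2, c_hb)
        upstream = (op_maps[w1].qc != 0) | (op_maps[w2].qc != 0)
        sto2_map.qc[upstream] |= QC_UPSTREAM_OUT_OF_LUT
    except Exception as exc:
        raise RuntimeError(f"{stage}: {exc}") from exc

    roi_table = None
    if roi_masks:
        stage = "roi_analysis"
        try:
            interior = np.zeros(sto2_map.sto2.shape, dtype=bool)
            if margin > 0:
                interior[:, margin:-margin] = True
            else:
                interior[:] = True
            masks = {k: np.asarray(v, bool) & interior for k, v in roi_masks.items()}
            roi_table = extract_roi_means(sto2_map, masks, subject=subject)
        except Exception as exc:
            raise RuntimeError(f"{stage}: {exc}") from exc

    qc_summary = {
        "pixels_out_of_lut": int(
            sum(int((m.qc != 0).sum()) for m in op_maps.values())
        ),
        "pixels_flagged_sto2": int((sto2_map.qc != 0).sum()),
        "edge_margin": int(margin),
    }
    run_log = {"config_hash": config.content_hash(), "method": method}

    result = PipelineResult(
        modulation=modulation, reflectance=reflectance, optical_properties=op_maps,
        sto2_map=sto2_map, roi_table=roi_table, method=method or "",
        edge_margin=margin, qc_summary=qc_summary, run_log=run_log,
    )
    if output_dir is not None:
        _persist(result, Path(output_dir))
    return result


def _persist(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for w, m in result.modulation.items():
        sio.write_map(out / f"m_dc_{w:g}nm.tif", m.m_dc)
        sio.write_map(out / f"m_ac_{w:g}nm.tif", m.m_ac)
    for w, r in result.reflectance.items():
        sio.write_map(out / f"rd_dc_{w:g}nm.tif", r.rd_dc)
        sio.write_map(out / f"rd_ac_{w:g}nm.tif", r.rd_ac)
    for w, p in result.optical_properties.items():
        sio.write_map(out / f"mu_a_{w:g}nm.tif", p.mu_a)
        sio.write_map(out / f"mu_s_prime_{w:g}nm.tif", p.mu_s_prime)
    sio.write_map(out / "sto2.tif", result.sto2_map.sto2)
    import tifffile

    tifffile.imwrite(out / "sto2_qc.tif", result.sto2_map.qc.astype(np.uint8))
    if result.roi_table is not None:
        result.roi_table.to_csv(out / "roi_timeseries.csv", index=False)
    (out / "run_log.json").write_text(
        json.dumps({**result.run_log, "qc": result.qc_summary}, indent=1)
    )
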
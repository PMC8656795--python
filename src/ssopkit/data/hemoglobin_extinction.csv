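# Molar extinction coefficients of human oxy- and deoxy-hemoglobin,
# base-10 (decadic) convention, units cm^-1 / (mol/L), per heme-equivalent
# tetramer basis as in the standard compiled literature spectra
# (van Assendelft / OMLC-style compilation, interpolated to a 10 nm grid).
# mu_a [mm^-1] = ln(10) * eps [mm^-1 mM^-1] * C [mM], with
# eps [mm^-1 mM^-1] = 1e-4 * eps [cm^-1 M^-1].
# version: 1
wavelength_nm,eps_hbo2_cm1_M,eps_hb_cm1_M
600,3200.0,14677.2
610,1506.0,9443.6
620,942.0,6509.6
630,610.0,5148.8
640,442.0,4345.2
650,368.0,3750.1
660,319.6,3226.6
670,294.0,2795.1
680,277.6,2407.9
690,276.0,2051.9
700,290.0,1794.3
710,314.0,1540.5
720,348.0,1327.2
730,390.0,1168.9
740,446.0,1215.8
750,518.0,1405.2
760,586.0,1548.5
770,650.0,1311.9
780,710.0,1075.4
790,756.0,890.8
800,816.0,761.7
810,864.0,717.1
820,916.0,693.8
830,970.0,691.3
840,1022.0,692.4
850,1058.0,691.3
860,1092.0,700.0
870,1124.0,712.0
880,1154.0,726.4
890,1178.0,743.0
900,1198.0,761.8
910,1220.0,782.0
920,1264.0,804.7
930,1240.0,830.0
940,1214.0,860.0
950,1190.0,895.0
960,1170.0,930.0
970,1150.0,965.0
980,1130.0,1000.0
990,1090.0,1025.0
1000,1050.0,1050.0
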
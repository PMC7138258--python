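# Molar extinction coefficients of human hemoglobin in the near infrared.
# Compiled tabulated values; units: cm^-1 / (mol/L), decadic (base-10).
# wavelength_nm	eps_hbo2	eps_hb
700	290.0	1794.28
710	316.0	1540.48
720	348.0	1325.88
730	390.0	1102.20
740	446.0	1115.88
750	518.0	1405.24
760	586.0	1548.52
770	650.0	1311.88
780	710.0	1075.44
790	762.0	890.80
800	816.0	761.84
810	864.0	717.08
820	916.0	693.04
830	974.0	693.04
840	1022.0	693.76
850	1058.0	691.32
860	1092.0	692.36
870	1128.0	695.00
880	1154.0	702.00
890	1178.0	711.00
900	1198.0	724.00
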
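# Molar extinction coefficients of human haemoglobin, 650-900 nm.
# Standard literature compilation (tabulated whole-blood spectrophotometry),
# linearly interpolated between grid points by the unmixing module.
# Units: cm^-1 / (mol/L). Columns: wavelength_nm, eps_hb (deoxy), eps_hbo2 (oxy).
wavelength_nm	eps_hb	eps_hbo2
650	3750.12	368.00
660	3226.56	319.60
670	2795.12	294.00
680	2407.92	277.60
690	2051.96	276.00
700	1794.28	290.00
710	1540.48	314.00
720	1325.88	348.00
730	1102.20	390.00
740	1200.80	446.00
750	1405.24	518.00
760	1548.52	586.00
770	1311.88	650.00
780	1075.44	710.00
790	898.04	756.00
800	761.72	816.00
810	717.08	864.00
820	693.76	916.00
830	693.04	974.00
840	692.36	1022.00
850	691.32	1058.00
860	691.96	1092.00
870	700.00	1128.00
880	726.44	1154.00
890	743.60	1178.00
900	761.84	1198.00
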
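# Molar absorption coefficients of oxy- and deoxy-hemoglobin (1/(cm*M)),
# approximate values digitized from standard published compilations of
# hemoglobin optical absorption; linearly interpolated between rows.
wavelength_nm,HbO2,Hb
700,290.0,1794.3
710,320.0,1500.0
720,356.0,1280.0
730,390.0,1102.2
740,446.0,1115.9
750,518.0,1405.2
760,586.0,1548.5
770,650.0,1311.9
780,710.0,1075.4
790,774.0,890.8
800,816.0,761.7
810,864.0,717.1
820,916.0,693.8
830,974.0,693.0
840,1022.0,692.4
850,1058.0,691.3
860,1092.0,691.0
870,1128.0,696.0
880,1154.0,711.0
890,1178.0,724.0
900,1198.0,730.0
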
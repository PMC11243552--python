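Ligand	E_protein–ligand_	E_total_	Steric	van der Waals	Hydrogen Bond	Binding Affinity	Provenance
4,5,6,7-tetrabromo-	−81.75	−60.95	−80.65	−24.66	−1.09	−9.45	rio1:1
4,5,6,7-tetrachloro-	−86.01	−64.41	−85.09	−23.19	−0.93	−9.44	rio1:2
4,5,6,7-tetraiodo-	−75.61	−57.06	−75.61	−25.47	0	−9.32	rio1:3
5,6-dibromo-	−81.87	−71.31	−79.97	−22.28	−1.90	−7.91	rio1:4
5,6-dichloro-	−84.21	−73.30	−82.23	−21.75	−1.99	−7.92	rio1:5
5,6-diiodo-	−79.76	−69.26	−77.74	−21.75	−2.03	−7.93	rio1:6
5,6-dibromo,4,7-dichloro-	−83.77	−64.10	−82.95	−22.97	−0.82	−9.43	rio1:7
5,6-dibromo,4,7-diiodo-	−80.14	−61.61	−80.14	−27.26	0	−9.32	rio1:8
5,6-diiodo,4,7-dibromo-	−79.29	−60.33	−78.86	−24.06	−0.43	−9.38	rio1:9
5,6-diiodo,4,7-dichloro-	−81.66	−62.87	−80.77	−22.98	−0.90	−9.43	rio1:10
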
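Ligand	E_protein–ligand_	E_total_	Steric	van der Waals	Hydrogen Bonds	Binding Affinity	Provenance
4,5,6,7-tetrabromo-	−91.79	−77.06	−87.79	−15.63	−4.00	−9.80	pim1:1
4,5,6,7-tetrachloro-	−96.61	−79.36	−92.83	−19.63	−3.79	−9.78	pim1:2
4,5,6,7-tetraiodo-	−83.33	−70.88	−79.35	−21.12	−3.98	−9.79	pim1:3
5,6-dibromo-	−94.13	−81.73	−89.13	−18.71	−5.00	−8.29	pim1:4
5,6-dichloro-	−96.82	−83.81	−91.82	−18.87	−5.00	−8.29	pim1:5
5,6-diiodo-	−90.29	−78.04	−85.29	−18.55	−5.00	−8.29	pim1:6
5,6-dibromo,4,7-dichloro-	−91.90	−76.44	−87.97	−20.62	−3.93	−9.79	pim1:7
5,6-dibromo,4,7-diiodo-	−88.96	−76.35	−84.99	−21.96	−3.97	−9.79	pim1:8
5,6-diiodo,4,7-dibromo-	−85.14	−71.34	−81.18	−20.38	−3.96	−9.79	pim1:9
5,6-diiodo,4,7-dichloro-	−86.87	−72.25	−82.89	−20.36	−3.97	−9.80	pim1:10
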
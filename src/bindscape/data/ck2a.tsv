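Glycone	Ligand	E_protein–ligand	E_total	Steric	van der Waals	Hydrogen Bond	Binding Affinity	Provenance
-	4,5,6,7-tetrabromo-	−66.69	−67.37	−66.69	−15.54	0	−8.67	ck2a:1
-	4,5,6,7-tetrachloro-	−68.56	−66.16	−68.56	−15.93	0	−8.67	ck2a:2
-	4,5,6,7-tetraiodo-	−64.90	−66.47	−64.90	−14.95	0	−8.67	ck2a:3
-	5,6-dibromo-	−71.53	−69.37	−69.68	−19.98	−1.85	−7.16	ck2a:4
-	5,6-dichloro-	−72.38	−69.70	−70.48	−20.28	−1.90	−7.17	ck2a:5
-	5,6-diiodo-	−70.93	−68.88	−69.28	−19.37	−1.65	−7.14	ck2a:6
-	5,6-dibromo,4,7-dichloro-	−66.79	−66.43	−66.79	−15.60	0	−8.61	ck2a:7
-	5,6-dibromo,4,7-diiodo-	−65.27	−67.01	−65.27	−15.04	0	−8.61	ck2a:8
-	5,6-diiodo,4,7-dibromo-	−64.88	−66.72	−64.88	−14.94	0	−8.60	ck2a:9
-	5,6-diiodo,4,7-dichloro-	−64.76	−65.50	−64.76	−14.85	0	−8.61	ck2a:10
ribose	4,5,6,7-tetrabromo-	−81.88	−82.32	−78.84	−18.54	−3.04	−7.56	ck2a:11
ribose	4,5,6,7-tetrachloro-	−83.69	−80.81	−80.61	−18.69	−3.08	−7.56	ck2a:12
ribose	4,5,6,7-tetraiodo-	−79.43	−81.02	−76.59	−18.13	−2.83	−7.54	ck2a:13
ribose	5,6-dibromo-	−72.79	−69.69	−70.11	−21.02	−2.68	−5.83	ck2a:14
ribose	5,6-dichloro-	−73.40	−69.78	−70.69	−20.92	−2.70	−5.83	ck2a:15
ribose	5,6-diiodo-	−73.09	−70.32	−70.59	−22.38	−2.50	−5.81	ck2a:16
ribose	5,6-dibromo,4,7-dichloro-	−85.28	−83.80	−80.40	−18.20	−4.88	−7.72	ck2a:17
ribose	5,6-dibromo,4,7-diiodo-	−80.70	−82.01	−75.94	−17.49	−4.76	−7.71	ck2a:18
ribose	5,6-diiodo,4,7-dibromo-	−81.15	−82.32	−77.76	−17.24	−3.39	−7.55	ck2a:19
ribose	5,6-diiodo,4,7-dichloro-	−84.41	−84.04	−79.54	−16.90	−4.86	−7.72	ck2a:20
2′-deoxyribose	4,5,6,7-tetrabromo-	−83.33	−81.57	−80.83	−22.47	−2.50	−8.06	ck2a:21
2′-deoxyribose	4,5,6,7-tetrachloro-	−84.93	−86.28	−82.43	−22.55	−2.50	−7.94	ck2a:22
2′-deoxyribose	4,5,6,7-tetraiodo-	−79.78	−85.01	−77.28	−22.45	−2.50	−7.94	ck2a:23
2′-deoxyribose	5,6-dibromo-	−71.57	−71.27	−69.07	−22.34	−2.50	−6.29	ck2a:24
2′-deoxyribose	5,6-dichloro-	−72.54	−71.98	−70.04	−22.40	−2.50	−6.29	ck2a:25
2′-deoxyribose	5,6-diiodo-	−71.09	−70.96	−68.59	−22.48	−2.50	−6.29	ck2a:26
2′-deoxyribose	5,6-dibromo,4,7-dichloro-	−84.10	−87.25	−81.60	−22.47	−2.50	−7.94	ck2a:27
2′-deoxyribose	5,6-dibromo,4,7-diiodo-	−81.00	−86.09	−78.50	−22.67	−2.50	−7.94	ck2a:28
2′-deoxyribose	5,6-diiodo,4,7-dibromo-	−81.82	−86.77	−79.32	−22.48	−2.50	−7.94	ck2a:29
2′-deoxyribose	5,6-diiodo,4,7-dichloro-	−83.07	−87.08	−80.57	−22.46	−2.50	−7.94	ck2a:30
2′-deoxy-2′,2′-difluoro-ribose	4,5,6,7-tetrabromo-	−77.05	−61.06	−75.30	−22.63	−1.76	−9.53	ck2a:31
2′-deoxy-2′,2′-difluoro-ribose	4,5,6,7-tetrachloro-	−77.84	−60.06	−76.16	−22.65	−1.69	−9.52	ck2a:32
2′-deoxy-2′,2′-difluoro-ribose	4,5,6,7-tetraiodo-	−77.73	−63.48	−75.38	−22.87	−2.35	−9.59	ck2a:33
2′-deoxy-2′,2′-difluoro-ribose	5,6-dibromo-	−65.83	−44.21	−64.10	−22.71	−1.73	−7.89	ck2a:34
2′-deoxy-2′,2′-difluoro-ribose	5,6-dichloro-	−67.34	−44.52	−65.58	−22.97	−1.76	−7.89	ck2a:35
2′-deoxy-2′,2′-difluoro-ribose	5,6-diiodo-	−66.60	−44.22	−64.62	−22.81	−1.98	−7.92	ck2a:36
2′-deoxy-2′,2′-difluoro-ribose	5,6-dibromo,4,7-dichloro-	−77.45	−61.53	−75.75	−22.62	−1.70	−9.52	ck2a:37
2′-deoxy-2′,2′-difluoro-ribose	5,6-dibromo,4,7-diiodo-	−74.65	−60.67	−72.94	−22.68	−1.70	−9.52	ck2a:38
2′-deoxy-2′,2′-difluoro-ribose	5,6-diiodo,4,7-dibromo-	−76.62	−62.32	−74.88	−22.47	−1.74	−9.53	ck2a:39
2′-deoxy-2′,2′-difluoro-ribose	5,6-diiodo,4,7-dichloro-	−76.60	−61.45	−74.92	−22.57	−1.68	−9.52	ck2a:40
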
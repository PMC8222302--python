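SYN01	synthetic pathway 1	GENE0058	GENE0067	GENE0105	GENE0123	GENE0134	GENE0156	GENE0226	GENE0231	GENE0267	GENE0490	GENE0584	GENE0638	GENE0663	GENE0670	GENE0676	GENE0729	GENE0736
SYN02	synthetic pathway 2	GENE0048	GENE0053	GENE0093	GENE0111	GENE0149	GENE0155	GENE0196	GENE0197	GENE0200	GENE0201	GENE0233	GENE0247	GENE0268	GENE0319	GENE0324	GENE0345	GENE0368	GENE0427	GENE0522	GENE0552	GENE0570	GENE0577	GENE0584	GENE0590	GENE0596	GENE0602	GENE0634	GENE0717	GENE0734
SYN03	synthetic pathway 3	GENE0018	GENE0063	GENE0091	GENE0134	GENE0168	GENE0249	GENE0255	GENE0335	GENE0400	GENE0499	GENE0509	GENE0514
SYN04	synthetic pathway 4	GENE0006	GENE0010	GENE0012	GENE0032	GENE0035	GENE0037	GENE0040	GENE0093	GENE0144	GENE0178	GENE0238	GENE0249	GENE0291	GENE0303	GENE0355	GENE0362	GENE0379	GENE0396	GENE0398	GENE0403	GENE0420	GENE0438	GENE0444	GENE0484	GENE0683	GENE0689	GENE0712	GENE0718
SYN05	synthetic pathway 5	GENE0024	GENE0074	GENE0097	GENE0098	GENE0146	GENE0160	GENE0204	GENE0245	GENE0279	GENE0295	GENE0399	GENE0404	GENE0468	GENE0504	GENE0510	GENE0556	GENE0623	GENE0691
SYN06	synthetic pathway 6	GENE0008	GENE0012	GENE0015	GENE0094	GENE0176	GENE0179	GENE0190	GENE0280	GENE0308	GENE0322	GENE0348	GENE0352	GENE0353	GENE0363	GENE0437	GENE0440	GENE0454	GENE0469	GENE0484	GENE0524	GENE0573	GENE0621	GENE0622	GENE0662	GENE0735
SYN07	synthetic pathway 7	GENE0038	GENE0044	GENE0053	GENE0063	GENE0095	GENE0101	GENE0171	GENE0190	GENE0228	GENE0264	GENE0272	GENE0274	GENE0283	GENE0415	GENE0429	GENE0430	GENE0658	GENE0670	GENE0678
SYN08	synthetic pathway 8	GENE0005	GENE0020	GENE0065	GENE0134	GENE0152	GENE0161	GENE0162	GENE0184	GENE0192	GENE0198	GENE0222	GENE0224	GENE0255	GENE0354	GENE0371	GENE0403	GENE0458	GENE0471	GENE0483	GENE0500	GENE0537	GENE0568	GENE0569	GENE0589	GENE0598	GENE0612	GENE0628	GENE0651	GENE0655	GENE0669	GENE0670	GENE0690	GENE0708	GENE0727	GENE0739
SYN09	synthetic pathway 9	GENE0028	GENE0050	GENE0070	GENE0071	GENE0126	GENE0130	GENE0141	GENE0144	GENE0153	GENE0204	GENE0271	GENE0272	GENE0319	GENE0320	GENE0356	GENE0368	GENE0480	GENE0486	GENE0490	GENE0514	GENE0537	GENE0554	GENE0559	GENE0592	GENE0624	GENE0647	GENE0652	GENE0680	GENE0697	GENE0699	GENE0703	GENE0717	GENE0721	GENE0724	GENE0738
SYN10	synthetic pathway 10	GENE0032	GENE0130	GENE0291	GENE0348	GENE0401	GENE0423	GENE0470	GENE0479	GENE0486	GENE0544	GENE0601	GENE0628	GENE0703
SYN11	synthetic pathway 11	GENE0093	GENE0128	GENE0148	GENE0164	GENE0227	GENE0234	GENE0299	GENE0303	GENE0472	GENE0515	GENE0538	GENE0554	GENE0559	GENE0574	GENE0631	GENE0659	GENE0679	GENE0694	GENE0723
SYN12	synthetic pathway 12	GENE0018	GENE0047	GENE0090	GENE0099	GENE0101	GENE0148	GENE0174	GENE0192	GENE0226	GENE0482	GENE0514	GENE0561	GENE0607	GENE0609	GENE0635	GENE0646	GENE0668	GENE0682	GENE0693
SYN13	synthetic pathway 13	GENE0006	GENE0026	GENE0054	GENE0112	GENE0143	GENE0152	GENE0201	GENE0273	GENE0275	GENE0339	GENE0359	GENE0363	GENE0380	GENE0390	GENE0412	GENE0430	GENE0438	GENE0445	GENE0461	GENE0552	GENE0555	GENE0593	GENE0658	GENE0684
SYN14	synthetic pathway 14	GENE0009	GENE0012	GENE0123	GENE0126	GENE0192	GENE0210	GENE0217	GENE0298	GENE0411	GENE0439	GENE0501	GENE0512	GENE0566	GENE0683
SYN15	synthetic pathway 15	GENE0007	GENE0010	GENE0016	GENE0036	GENE0059	GENE0079	GENE0097	GENE0114	GENE0161	GENE0180	GENE0203	GENE0217	GENE0221	GENE0270	GENE0293	GENE0303	GENE0308	GENE0321	GENE0322	GENE0338	GENE0345	GENE0354	GENE0365	GENE0366	GENE0393	GENE0420	GENE0421	GENE0456	GENE0461	GENE0466	GENE0489	GENE0530	GENE0542	GENE0554	GENE0638	GENE0653	GENE0655
SYN16	synthetic pathway 16	GENE0024	GENE0104	GENE0107	GENE0180	GENE0267	GENE0291	GENE0311	GENE0360	GENE0379	GENE0381	GENE0390	GENE0404	GENE0440	GENE0519	GENE0539	GENE0564
SYN17	synthetic pathway 17	GENE0025	GENE0033	GENE0035	GENE0038	GENE0049	GENE0058	GENE0077	GENE0127	GENE0145	GENE0214	GENE0231	GENE0416	GENE0470	GENE0477	GENE0560	GENE0581	GENE0588	GENE0623	GENE0641	GENE0681
SYN18	synthetic pathway 18	GENE0014	GENE0029	GENE0037	GENE0054	GENE0055	GENE0071	GENE0091	GENE0152	GENE0186	GENE0213	GENE0217	GENE0253	GENE0254	GENE0269	GENE0289	GENE0293	GENE0300	GENE0328	GENE0360	GENE0373	GENE0379	GENE0399	GENE0416	GENE0420	GENE0421	GENE0458	GENE0473	GENE0488	GENE0536	GENE0540	GENE0554	GENE0556	GENE0623	GENE0671	GENE0679	GENE0713	GENE0724	GENE0728
SYN19	synthetic pathway 19	GENE0006	GENE0019	GENE0063	GENE0108	GENE0115	GENE0181	GENE0196	GENE0223	GENE0293	GENE0311	GENE0313	GENE0334	GENE0335	GENE0336	GENE0392	GENE0418	GENE0437	GENE0479	GENE0571	GENE0579	GENE0585	GENE0590	GENE0616	GENE0627	GENE0651	GENE0672	GENE0691
SYN20	synthetic pathway 20	GENE0003	GENE0007	GENE0011	GENE0025	GENE0075	GENE0152	GENE0171	GENE0193	GENE0207	GENE0238	GENE0264	GENE0287	GENE0315	GENE0370	GENE0403	GENE0413	GENE0501	GENE0503	GENE0510	GENE0522	GENE0525	GENE0655	GENE0663	GENE0680	GENE0694
SYN21	synthetic pathway 21	GENE0005	GENE0046	GENE0131	GENE0148	GENE0156	GENE0178	GENE0186	GENE0227	GENE0372	GENE0397	GENE0424	GENE0437	GENE0465	GENE0516	GENE0519	GENE0521	GENE0541	GENE0550	GENE0573	GENE0588	GENE0593	GENE0612	GENE0661	GENE0676	GENE0681	GENE0698	GENE0732
SYN22	synthetic pathway 22	GENE0110	GENE0140	GENE0151	GENE0161	GENE0168	GENE0185	GENE0220	GENE0258	GENE0261	GENE0342	GENE0343	GENE0350	GENE0370	GENE0456	GENE0467	GENE0519	GENE0545	GENE0585	GENE0606	GENE0621	GENE0633	GENE0694	GENE0702	GENE0705	GENE0717
SYN23	synthetic pathway 23	GENE0010	GENE0014	GENE0087	GENE0093	GENE0105	GENE0122	GENE0125	GENE0137	GENE0140	GENE0148	GENE0164	GENE0166	GENE0199	GENE0240	GENE0249	GENE0289	GENE0294	GENE0298	GENE0329	GENE0341	GENE0394	GENE0396	GENE0449	GENE0451	GENE0455	GENE0457	GENE0462	GENE0474	GENE0506	GENE0520	GENE0576	GENE0612	GENE0639	GENE0653	GENE0669	GENE0691	GENE0702
SYN24	synthetic pathway 24	GENE0002	GENE0007	GENE0026	GENE0054	GENE0079	GENE0142	GENE0160	GENE0185	GENE0214	GENE0237	GENE0270	GENE0293	GENE0315	GENE0333	GENE0357	GENE0379	GENE0425	GENE0427	GENE0466	GENE0468	GENE0472	GENE0475	GENE0487	GENE0504	GENE0510	GENE0535	GENE0536	GENE0557	GENE0574	GENE0586	GENE0593	GENE0594	GENE0604	GENE0608	GENE0657	GENE0679	GENE0692	GENE0700
SYN25	synthetic pathway 25	GENE0005	GENE0037	GENE0088	GENE0118	GENE0239	GENE0312	GENE0360	GENE0449	GENE0468	GENE0516	GENE0529	GENE0541	GENE0561	GENE0606	GENE0699
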